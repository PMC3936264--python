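"""Readers and writers for the pipeline's file formats.

Corpora, gold annotations and mentions travel as JSONL (one object per
line, streamable); the registry, demographics and analysis tables as
UTF-8 CSV.  Every table write leaves a ``<name>.meta.json`` sidecar with
the configuration hash and seed for provenance.  Readers validate
schemas and report the offending line or row on failure.
"""

from __future__ import annotations

import hashlib
import json
from pathlib import Path
from typing import Any, Iterable, Sequence

import pandas as pd

from .corpus import AliasDictionary, GroundTruth, Hospital, MentionRecord, Message, Thread

__all__ = [
    "config_hash",
    "write_registry_csv",
    "read_registry_csv",
    "write_aliases_json",
    "read_aliases_json",
    "write_corpus_jsonl",
    "read_corpus_jsonl",
    "write_gold_jsonl",
    "read_gold_jsonl",
    "write_mentions_jsonl",
    "read_mentions_jsonl",
    "write_demographics_csv",
    "read_demographics_csv",
    "write_table_csv",
    "write_report_json",
]


def config_hash(config: Any) -> str:
    """Stable short hash of a JSON-serializable configuration mapping."""
    payload = json.dumps(config, sort_keys=True, default=str)
    return hashlib.sha256(payload.encode("utf-8")).hexdigest()[:16]


def _write_sidecar(path: Path, meta: dict | None) -> None:
    if meta is None:
        return
    sidecar = path.with_suffix(path.suffix + ".meta.json")
    sidecar.write_text(
        json.dumps(meta, sort_keys=True, indent=2, default=str) + "\n",
        encoding="utf-8",
    )


# ---------------------------------------------------------------------------
# registry


_REGISTRY_COLUMNS = [
    "hospital_id",
    "canonical_name",
    "district_id",
    "antibiotic_rate",
    "n_doctors",
]


def write_registry_csv(
    registry: Sequence[Hospital], path, meta: dict | None = None
) -> None:
    path = Path(path)
    df = pd.DataFrame(
        [
            {
                "hospital_id": h.hospital_id,
                "canonical_name": h.canonical_name,
                "district_id": h.district_id,
                "antibiotic_rate": repr(h.antibiotic_rate),
                "n_doctors": h.n_doctors,
            }
            for h in registry
        ],
        columns=_REGISTRY_COLUMNS,
    )
    df.to_csv(path, index=False, encoding="utf-8")
    _write_sidecar(path, meta)


def read_registry_csv(path) -> list[Hospital]:
    df = pd.read_csv(path, encoding="utf-8", dtype={c: str for c in _REGISTRY_COLUMNS})
    missing = [c for c in _REGISTRY_COLUMNS if c not in df.columns]
    if missing:
        raise ValueError(f"{path}: registry CSV missing columns {missing}")
    out = []
    for i, row in enumerate(df.itertuples(index=False), start=2):
        try:
            out.append(
                Hospital(
                    hospital_id=row.hospital_id,
                    canonical_name=row.canonical_name,
                    district_id=row.district_id,
                    antibiotic_rate=float(row.antibiotic_rate),
                    n_doctors=int(row.n_doctors),
                )
            )
        except (TypeError, ValueError) as err:
            raise ValueError(f"{path}: invalid registry row at line {i}: {err}") from err
    return out


# ---------------------------------------------------------------------------
# aliases


def write_aliases_json(
    aliases: AliasDictionary, path, meta: dict | None = None
) -> None:
    path = Path(path)
    payload = {
        canonical: {
            "hospital_id": aliases.hospital_ids.get(canonical, canonical),
            "aliases": sorted(forms),
        }
        for canonical, forms in sorted(aliases.entries.items())
    }
    path.write_text(
        json.dumps(payload, sort_keys=True, ensure_ascii=False, indent=1) + "\n",
        encoding="utf-8",
    )
    _write_sidecar(path, meta)


def read_aliases_json(path) -> AliasDictionary:
    payload = json.loads(Path(path).read_text(encoding="utf-8"))
    entries: dict[str, set[str]] = {}
    hospital_ids: dict[str, str] = {}
    for canonical, spec in payload.items():
        if not isinstance(spec, dict) or "aliases" not in spec:
            raise ValueError(f"{path}: entry {canonical!r} must map to "
                             "{'hospital_id': ..., 'aliases': [...]}")
        entries[canonical] = set(spec["aliases"])
        hospital_ids[canonical] = spec.get("hospital_id", canonical)
    return AliasDictionary(entries=entries, hospital_ids=hospital_ids)


# ---------------------------------------------------------------------------
# corpus / gold / mentions (JSONL)


_MESSAGE_FIELDS = ("message_id", "thread_id", "district_id", "is_reply", "text")


def write_corpus_jsonl(messages: Sequence[Message], path, meta: dict | None = None) -> None:
    path = Path(path)
    with path.open("w", encoding="utf-8") as fh:
        for m in messages:
            fh.write(
                json.dumps(
                    {
                        "message_id": m.message_id,
                        "thread_id": m.thread_id,
                        "district_id": m.district_id,
                        "is_reply": m.is_reply,
                        "text": m.text,
                        "sentiment": m.sentiment,
                    },
                    ensure_ascii=False,
                    sort_keys=True,
                )
                + "\n"
            )
    _write_sidecar(path, meta)


def _iter_jsonl(path) -> Iterable[tuple[int, dict]]:
    with Path(path).open("r", encoding="utf-8") as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.strip()
            if not line:
                continue
            try:
                obj = json.loads(line)
            except json.JSONDecodeError as err:
                raise ValueError(f"{path}: malformed JSON at line {lineno}: {err}") from err
            yield lineno, obj


def read_corpus_jsonl(path) -> tuple[list[Thread], list[Message]]:
    messages: list[Message] = []
    seen_ids: set[str] = set()
    thread_district: dict[str, str] = {}
    for lineno, obj in _iter_jsonl(path):
        for f in _MESSAGE_FIELDS:
            if f not in obj:
                raise ValueError(f"{path}: line {lineno} missing field {f!r}")
        if obj["message_id"] in seen_ids:
            raise ValueError(
                f"{path}: duplicate message_id {obj['message_id']!r} at line {lineno}"
            )
        seen_ids.add(obj["message_id"])
        messages.append(
            Message(
                message_id=obj["message_id"],
                thread_id=obj["thread_id"],
                district_id=obj["district_id"],
                is_reply=bool(obj["is_reply"]),
                text=obj["text"],
                sentiment=obj.get("sentiment", "unlabeled"),
            )
        )
        thread_district.setdefault(obj["thread_id"], obj["district_id"])
    threads = [
        Thread(thread_id=t, district_id=d) for t, d in sorted(thread_district.items())
    ]
    return threads, messages


def write_gold_jsonl(gold: GroundTruth, path, meta: dict | None = None) -> None:
    path = Path(path)
    with path.open("w", encoding="utf-8") as fh:
        for mid in sorted(gold.mentions):
            fh.write(
                json.dumps(
                    {
                        "type": "mentions",
                        "message_id": mid,
                        "hospital_ids": sorted(gold.mentions[mid]),
                    },
                    sort_keys=True,
                )
                + "\n"
            )
        for district in sorted(gold.perceived_ranking):
            fh.write(
                json.dumps(
                    {
                        "type": "district",
                        "district_id": district,
                        "perceived_ranking": gold.perceived_ranking[district],
                        "noise_sd": repr(gold.noise_sd.get(district, 0.0)),
                    },
                    sort_keys=True,
                )
                + "\n"
            )
    _write_sidecar(path, meta)


def read_gold_jsonl(path) -> GroundTruth:
    mentions: dict[str, set[str]] = {}
    ranking: dict[str, list[str]] = {}
    noise: dict[str, float] = {}
    for lineno, obj in _iter_jsonl(path):
        kind = obj.get("type")
        if kind == "mentions":
            if "message_id" not in obj or "hospital_ids" not in obj:
                raise ValueError(f"{path}: line {lineno}: incomplete mentions record")
            mentions[obj["message_id"]] = set(obj["hospital_ids"])
        elif kind == "district":
            ranking[obj["district_id"]] = list(obj.get("perceived_ranking", []))
            noise[obj["district_id"]] = float(obj.get("noise_sd", 0.0))
        else:
            raise ValueError(f"{path}: line {lineno}: unknown record type {kind!r}")
    return GroundTruth(mentions=mentions, perceived_ranking=ranking, noise_sd=noise)


def write_mentions_jsonl(
    mentions: Sequence[MentionRecord], path, meta: dict | None = None
) -> None:
    path = Path(path)
    with path.open("w", encoding="utf-8") as fh:
        for m in mentions:
            fh.write(
                json.dumps(
                    {
                        "message_id": m.message_id,
                        "hospital_id": m.hospital_id,
                        "surface_form": m.surface_form,
                        "distance": m.distance,
                        "sentiment": m.sentiment,
                    },
                    ensure_ascii=False,
                    sort_keys=True,
                )
                + "\n"
            )
    _write_sidecar(path, meta)


def read_mentions_jsonl(path) -> list[MentionRecord]:
    out = []
    for lineno, obj in _iter_jsonl(path):
        try:
            out.append(
                MentionRecord(
                    message_id=obj["message_id"],
                    hospital_id=obj["hospital_id"],
                    surface_form=obj["surface_form"],
                    distance=int(obj["distance"]),
                    sentiment=obj.get("sentiment", "unlabeled"),
                )
            )
        except (KeyError, TypeError, ValueError) as err:
            raise ValueError(f"{path}: invalid mention at line {lineno}: {err}") from err
    return out


# ---------------------------------------------------------------------------
# demographics / tables / report


_DEMOGRAPHICS_COLUMNS = [
    "district_id",
    "birthrate",
    "education_mean",
    "education_sd",
    "population",
    "area_km2",
    "population_density",
    "doctors_per_clinic",
    "availability",
]


def write_demographics_csv(demographics, path, meta: dict | None = None) -> None:
    from .demographics import demographics_frame

    path = Path(path)
    if not isinstance(demographics, pd.DataFrame):
        demographics = demographics_frame(demographics)
    df = demographics.reset_index()
    missing = [c for c in _DEMOGRAPHICS_COLUMNS if c not in df.columns]
    if missing:
        raise ValueError(f"demographics table missing columns {missing}")
    df[_DEMOGRAPHICS_COLUMNS].to_csv(
        path, index=False, encoding="utf-8", float_format="%.12g"
    )
    _write_sidecar(path, meta)


def read_demographics_csv(path) -> pd.DataFrame:
    df = pd.read_csv(path, encoding="utf-8")
    missing = [c for c in _DEMOGRAPHICS_COLUMNS if c not in df.columns]
    if missing:
        raise ValueError(f"{path}: demographics CSV missing columns {missing}")
    return df.set_index("district_id")


def write_table_csv(df: pd.DataFrame, path, meta: dict | None = None, index: bool = False) -> None:
    path = Path(path)
    df.to_csv(path, index=index, encoding="utf-8", float_format="%.12g")
    _write_sidecar(path, meta)


def write_report_json(report: dict, path, meta: dict | None = None) -> None:
    path = Path(path)
    path.write_text(
        json.dumps(report, sort_keys=True, indent=2, default=str) + "\n",
        encoding="utf-8",
    )
    _write_sidecar(path, meta)
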