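"""Published summary statistics of the Korean study setting.

These numbers are inputs to the analysis, not outputs of this package:
corpus statistics of the Naver/Daum local parenting communities
(2009-2012), the human sentiment-annotation sample, the extraction
tagging sample, and census/HIRA covariate summaries for the 29 analyzed
metropolitan districts.  The synthetic generator uses the covariate
summaries as its default generative moments.
"""

from __future__ import annotations

import pandas as pd

# Threads and messages harvested per metropolitan region from the local
# parenting communities hosted on the Naver and Daum portals.
COMMUNITY_CONTENT_STATS = pd.DataFrame(
    {
        "region": ["Seoul", "Daegu", "Busan", "Daejeon", "Incheon", "Gwangju"],
        "threads": [10_832, 8_072, 5_965, 3_952, 775, 2_826],
        "messages": [54_392, 47_419, 28_910, 22_475, 5_184, 15_368],
    }
).set_index("region")

# Human sentiment annotation of a sample of the corpus: of 32,065 sampled
# messages, 29,511 were positive or neutral and 2,554 negative.
SENTIMENT_SAMPLE = {
    "total_messages": 173_748,
    "sampled_messages": 32_065,
    "positive_or_neutral": 29_511,
    "negative": 2_554,
}

# Human tagging sample used to score the extractor (recall 73%,
# precision 84% as published).
TAGGING_SAMPLE = {
    "total_messages": 173_748,
    "tagged_messages": 9_450,
    "precision": 0.84,
    "recall": 0.73,
}

# Census / HIRA covariate summaries over the 29 districts (mean, SD,
# min, max).  Population density is persons per m^2, i.e.
# population / (area_km2 * 1e6).
COVARIATE_SUMMARY = pd.DataFrame(
    {
        "mean": [1.048, 12.390, 3.496, 0.016, 1.641, 0.060],
        "sd": [0.100, 0.833, 0.183, 0.007, 0.396, 0.010],
        "min": [0.855, 11.340, 3.149, 0.003, 1.167, 0.033],
        "max": [1.261, 14.858, 3.788, 0.029, 2.889, 0.080],
    },
    index=pd.Index(
        [
            "birthrate",
            "education_mean",
            "education_sd",
            "population_density",
            "doctors_per_clinic",
            "availability",
        ],
        name="variable",
    ),
)

COVARIATES = list(COVARIATE_SUMMARY.index)

# Number of clinics mentioned in the online communities, per analyzed
# district (24 Seoul districts followed by the five other metropolitan
# cities); the counts sum to the 779 rank-ordered pediatric clinics.
DISTRICT_CLINIC_COUNTS = [
    14, 21, 11, 15, 15, 17, 11, 5, 22, 10, 11, 12,
    15, 13, 11, 11, 10, 26, 18, 15, 8, 16, 3, 12,
    57, 99, 53, 155, 93,
]

TOTAL_CLINICS = sum(DISTRICT_CLINIC_COUNTS)  # 779
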