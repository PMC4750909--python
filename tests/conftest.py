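"""Shared fixtures: a small lossless synthetic study and printed reference
values for the IOBS worked examples."""

from __future__ import annotations

import pytest

from oligocoi import SyntheticConfig, generate_dataset

# Published per-sample IOBS inputs and printed results for the six mixed
# oligochaete samples, on each abundance basis: (n_otus, pct_dominant
# tubificids, printed index as a string preserving printed precision,
# quality class from the table's typographic key).
TABLE3 = {
    "sanger": {
        "S1": (15, 77.5, "1.94", "poor"),
        "S2": (12, 80.95, "1.48", "poor"),
        "S3": (10, 85.19, "1.17", "poor"),
        "S4": (12, 56.0, "2.14", "medium"),
        "S5": (10, 46.88, "2.13", "medium"),
        "S6": (14, 44.12, "3.17", "good"),
    },
    "ngs_uncorrected": {
        "S1": (14, 80.47, "1.74", "poor"),
        "S2": (12, 81.26, "1.48", "poor"),
        "S3": (12, 85.4, "1.41", "poor"),
        "S4": (13, 37.07, "3.5", "good"),
        "S5": (10, 83.04, "1.2", "poor"),
        "S6": (17, 75.45, "2.25", "medium"),
    },
    "ngs_corrected": {
        "S1": (14, 74.53, "1.88", "poor"),
        "S2": (12, 85.41, "1.40", "poor"),
        "S3": (12, 92.17, "1.3", "poor"),
        "S4": (13, 76.84, "1.69", "poor"),
        "S5": (10, 57.88, "1.73", "poor"),
        "S6": (17, 62.77, "2.71", "medium"),
    },
}


LOSSLESS_CONFIG = SyntheticConfig(
    n_otus=8,
    seq_length=300,
    community_sizes=(30, 25, 20, 35),
    read_depth=300,
    per_base_error=0.0,
    quality_mean=40.0,
    quality_sd=0.0,
    read_length=150,
    rng_seed=11,
)


@pytest.fixture(scope="session")
def lossless_dataset(tmp_path_factory):
    """Four-sample synthetic study with error-free Q40 reads, written to
    disk once per session (FASTQ round trips are exact on it)."""
    out = tmp_path_factory.mktemp("lossless")
    return generate_dataset(LOSSLESS_CONFIG, out)
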