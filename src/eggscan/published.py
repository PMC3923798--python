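"""Reference accuracy tables from the original 150-egg candling experiment
that this pipeline emulates.

Each record is (feature, contrast, day, phase, mean, sd, cv): classification
accuracy in percent (mean ± sample sd over five repeated runs) and the
reported integer coefficient of variance, for the spectral mean-peak and
morphologic-rate features, both pairwise contrasts (N/D, D/W) and
incubation days 0-4.  'modeling' is training-set accuracy, 'prediction' is
testing-set accuracy.

These printed summaries are inputs for worked examples (the cv convention,
cv = 100·s/μ rounded half up, reproduces every printed cv cell); the
underlying per-egg data were never released, which is why the phantom
generator exists.
"""

from __future__ import annotations

__all__ = ["REFERENCE_RECORDS", "reference_cell"]

# (feature, contrast, day, phase, mean %, sd %, printed cv)
REFERENCE_RECORDS: list[tuple[str, str, int, str, int, int, int]] = [
    # spectral mean-peak feature
    ("spectral", "N/D", 0, "modeling", 73, 5, 7),
    ("spectral", "N/D", 0, "prediction", 65, 2, 3),
    ("spectral", "N/D", 1, "modeling", 74, 4, 5),
    ("spectral", "N/D", 1, "prediction", 63, 2, 3),
    ("spectral", "N/D", 2, "modeling", 72, 4, 6),
    ("spectral", "N/D", 2, "prediction", 60, 4, 7),
    ("spectral", "N/D", 3, "modeling", 81, 5, 6),
    ("spectral", "N/D", 3, "prediction", 77, 6, 8),
    ("spectral", "N/D", 4, "modeling", 85, 3, 4),
    ("spectral", "N/D", 4, "prediction", 83, 2, 2),
    ("spectral", "D/W", 0, "modeling", 67, 7, 10),
    ("spectral", "D/W", 0, "prediction", 69, 3, 4),
    ("spectral", "D/W", 1, "modeling", 72, 5, 7),
    ("spectral", "D/W", 1, "prediction", 72, 5, 7),
    ("spectral", "D/W", 2, "modeling", 73, 2, 3),
    ("spectral", "D/W", 2, "prediction", 66, 2, 3),
    ("spectral", "D/W", 3, "modeling", 83, 2, 2),
    ("spectral", "D/W", 3, "prediction", 80, 4, 5),
    ("spectral", "D/W", 4, "modeling", 86, 3, 3),
    ("spectral", "D/W", 4, "prediction", 82, 4, 5),
    # morphologic rate W feature
    ("morph", "N/D", 0, "modeling", 74, 3, 4),
    ("morph", "N/D", 0, "prediction", 72, 2, 3),
    ("morph", "N/D", 1, "modeling", 79, 4, 5),
    ("morph", "N/D", 1, "prediction", 70, 3, 4),
    ("morph", "N/D", 2, "modeling", 82, 1, 1),
    ("morph", "N/D", 2, "prediction", 76, 2, 3),
    ("morph", "N/D", 3, "modeling", 99, 0, 0),
    ("morph", "N/D", 3, "prediction", 97, 0, 0),
    ("morph", "N/D", 4, "modeling", 100, 0, 0),
    ("morph", "N/D", 4, "prediction", 100, 0, 0),
    ("morph", "D/W", 0, "modeling", 73, 5, 7),
    ("morph", "D/W", 0, "prediction", 73, 4, 5),
    ("morph", "D/W", 1, "modeling", 74, 4, 5),
    ("morph", "D/W", 1, "prediction", 71, 3, 4),
    ("morph", "D/W", 2, "modeling", 76, 3, 4),
    ("morph", "D/W", 2, "prediction", 70, 3, 4),
    ("morph", "D/W", 3, "modeling", 83, 2, 2),
    ("morph", "D/W", 3, "prediction", 81, 2, 2),
    ("morph", "D/W", 4, "modeling", 93, 1, 1),
    ("morph", "D/W", 4, "prediction", 92, 2, 2),
]


def reference_cell(feature: str, contrast: str, day: int,
                   phase: str) -> tuple[int, int, int]:
    """(mean, sd, printed cv) for one reference table cell."""
    for rec in REFERENCE_RECORDS:
        if rec[:4] == (feature, contrast, day, phase):
            return rec[4], rec[5], rec[6]
    raise KeyError((feature, contrast, day, phase))
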