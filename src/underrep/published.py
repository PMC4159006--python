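"""Reference counts from the original dm3 underreplicated-region survey.

These printed summary counts are inputs to the "replay" path: they let the
statistical machinery reproduce the published test statistics without access
to the original genome tracks. Each entry is (observed, expected, total) for
the two-cell goodness-of-fit, or raw 2x2 cells.
"""

from __future__ import annotations

import pandas as pd

from .enrichment import gof_chi_squared, pearson_chi2_2x2

#: genes with homologs in distant species among UR-assigned genes
#: (label, stratum) -> (observed, expected, total genes in stratum)
TABLE1_COUNTS: dict[tuple[str, str], tuple[int, float, int]] = {
    ("human_homolog", "all"): (104, 400.2, 933),
    ("human_homolog", "testis_specific"): (15, 27.9, 298),
    ("human_homolog", "other"): (80, 270.0, 544),
    ("mosquito_homolog", "all"): (506, 719.9, 933),
    ("mosquito_homolog", "testis_specific"): (129, 143.0, 298),
    ("mosquito_homolog", "other"): (343, 451.6, 544),
}

#: EST support among UR genes without vs. with D. virilis homologs:
#: (with-EST no-homolog, without-EST no-homolog, with-EST homolog, without-EST homolog)
EST_2X2 = (53, 11, 786, 83)

#: protein-length bookkeeping: (n genes, printed mean aa, outlier length aa)
UR_PROTEIN_MEAN = (933, 477.0)
UR_HUMAN_HOMOLOG_PROTEIN_MEAN = (104, 1114.0)
DUMPY_LENGTH = 22971  # the single extreme outlier protein

#: testis-specific census among UR genes with known expression pattern
TESTIS_COUNTS = (298, 842)


def replay_table1(counts: dict[tuple[str, str], tuple[int, float, int]] | None = None) -> pd.DataFrame:
    """Recompute the homolog-depletion statistics from printed counts."""
    counts = TABLE1_COUNTS if counts is None else counts
    rows = []
    for (label, stratum), (obs, exp, total) in counts.items():
        res = gof_chi_squared(obs, exp, total, category=stratum)
        rows.append(
            {
                "label": label,
                "stratum": stratum,
                "observed": obs,
                "expected": exp,
                "total": total,
                "exp_over_obs": exp / obs,
                "chi2": res.chi2,
                "p": res.p,
            }
        )
    return pd.DataFrame(rows)


def replay_est_2x2() -> tuple[float, float]:
    """Pearson chi-square (no continuity correction) on the printed EST table."""
    return pearson_chi2_2x2(*EST_2X2)


def mean_without_outlier(n: int, mean: float, outlier: float) -> float:
    """Arithmetic mean after removing one known value from a printed (n, mean)."""
    if n < 2:
        raise ValueError("need at least two entries to remove one")
    return (n * mean - outlier) / (n - 1)


def read_replay_counts(path) -> dict[tuple[str, str], tuple[int, float, int]]:
    """Replay input format: tab-delimited label, stratum, observed, expected, total."""
    out = {}
    with open(path) as fh:
        header = fh.readline().strip().split("\t")
        for line in fh:
            rec = dict(zip(header, line.rstrip("\n").split("\t")))
            out[(rec["label"], rec["stratum"])] = (
                int(rec["observed"]),
                float(rec["expected"]),
                int(rec["total"]),
            )
    return out
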