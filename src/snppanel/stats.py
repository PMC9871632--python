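"""Per-marker and summary genotype statistics.

All statistics are computed over non-missing calls only. For a biallelic
locus with ALT frequency p (q = 1 - p):

* expected heterozygosity (Nei gene diversity)  He = 2pq
* polymorphism information content              PIC = 1 - (p^2 + q^2) - 2 p^2 q^2
* minor allele frequency                        MAF = min(p, q)

PIC <= He always, with equality only at p in {0, 1}; the biallelic PIC
ceiling is 0.375 at p = 0.5. Per-marker genetic diversity (GD) is defined
identically to He and dataset GD is the unweighted mean across markers.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .containers import MISSING, GenotypeMatrix


class UndefinedStatisticError(ValueError):
    """Raised when a statistic is requested on an all-missing column."""


def call_rate(column: np.ndarray) -> float:
    """Fraction of samples with a genotype call at this marker."""
    column = np.asarray(column)
    if column.size == 0:
        raise ValueError("empty column")
    return float(np.count_nonzero(column != MISSING) / column.size)


def allele_freq_and_maf(column: np.ndarray) -> tuple[float, float]:
    """ALT allele frequency p = sum(dosage) / (2 * called) and min(p, 1-p)."""
    column = np.asarray(column)
    called = column[column != MISSING]
    if called.size == 0:
        raise UndefinedStatisticError("all calls missing; allele frequency undefined")
    p = float(called.sum() / (2 * called.size))
    return p, min(p, 1.0 - p)


def pic(p: float) -> float:
    """Biallelic polymorphism information content; symmetric in p <-> 1-p."""
    if not 0.0 <= p <= 1.0:
        raise ValueError(f"allele frequency out of [0,1]: {p}")
    q = 1.0 - p
    return 1.0 - (p * p + q * q) - 2.0 * p * p * q * q


def expected_het(p: float, n: int | None = None) -> float:
    """Nei gene diversity 2p(1-p).

    With ``n`` (number of called individuals) given, applies the
    small-sample correction 2p(1-p) * n/(n-1); the plug-in estimator is the
    default.
    """
    if not 0.0 <= p <= 1.0:
        raise ValueError(f"allele frequency out of [0,1]: {p}")
    he = 2.0 * p * (1.0 - p)
    if n is not None:
        if n < 2:
            raise ValueError("sample-size correction needs n >= 2")
        he *= n / (n - 1)
    return he


def observed_het(column: np.ndarray) -> float:
    """Fraction of heterozygous calls among non-missing calls."""
    column = np.asarray(column)
    called = column[column != MISSING]
    if called.size == 0:
        raise UndefinedStatisticError("all calls missing; Ho undefined")
    return float(np.count_nonzero(called == 1) / called.size)


def per_marker_stats(matrix: GenotypeMatrix) -> pd.DataFrame:
    """Table of call_rate, p, maf, pic, he, ho per marker.

    Markers with zero non-missing calls get NaN statistics (call_rate 0).
    """
    rows = []
    for j, m in enumerate(matrix.markers):
        col = matrix.column(j)
        cr = call_rate(col) if col.size else 0.0
        if cr == 0.0:
            rows.append((m.id, 0.0, np.nan, np.nan, np.nan, np.nan, np.nan))
            continue
        p, maf = allele_freq_and_maf(col)
        rows.append((m.id, cr, p, maf, pic(p), expected_het(p), observed_het(col)))
    return pd.DataFrame(
        rows, columns=["marker_id", "call_rate", "p", "maf", "pic", "he", "ho"]
    )


@dataclass
class StatsSummary:
    """Per-statistic (min, max, mean) overall and per group, Table-1 shaped."""

    overall: pd.DataFrame
    per_group: dict[str, pd.DataFrame]
    n_markers: int
    n_excluded: int  # markers with zero non-missing calls
    call_rate_mean: float
    call_rate_median: float

    def to_dict(self) -> dict:
        out = {
            "n_markers": self.n_markers,
            "n_excluded_all_missing": self.n_excluded,
            "call_rate": {
                "mean": self.call_rate_mean,
                "median": self.call_rate_median,
            },
            "overall": self.overall.to_dict(orient="index"),
            "groups": {
                g: df.to_dict(orient="index") for g, df in self.per_group.items()
            },
        }
        return out


def _summarize_frame(stats: pd.DataFrame) -> pd.DataFrame:
    cols = ["maf", "pic", "he", "ho"]
    ok = stats.dropna(subset=cols)
    return pd.DataFrame(
        {
            "min": ok[cols].min(),
            "max": ok[cols].max(),
            "mean": ok[cols].mean(),
        }
    )


def summarize(matrix: GenotypeMatrix, group_labels: list[str] | None = None) -> StatsSummary:
    """Overall and per-group statistic summary on a shared marker set.

    Group means are recomputed from group-restricted allele frequencies on
    the same markers; markers that are all-missing overall are excluded
    everywhere (count reported).
    """
    stats = per_marker_stats(matrix)
    excluded = int(stats["p"].isna().sum())
    if len(stats) - excluded == 0:
        raise UndefinedStatisticError("no marker with at least one call")

    if group_labels is None:
        group_labels = sorted({g for g in matrix.groups.values()})
    known = set(matrix.groups.values())
    bad = [g for g in group_labels if g not in known]
    if bad:
        raise ValueError(f"unknown group label(s): {bad}")

    keep = ~stats["p"].isna()
    per_group: dict[str, pd.DataFrame] = {}
    for g in group_labels:
        idx = [i for i, s in enumerate(matrix.samples) if matrix.groups.get(s) == g]
        if not idx:
            raise ValueError(f"group {g!r} has no samples")
        sub = per_marker_stats(matrix.subset_samples(idx))
        per_group[g] = _summarize_frame(sub[keep.values])

    return StatsSummary(
        overall=_summarize_frame(stats),
        per_group=per_group,
        n_markers=matrix.n_markers,
        n_excluded=excluded,
        call_rate_mean=float(stats["call_rate"].mean()),
        call_rate_median=float(stats["call_rate"].median()),
    )
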