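"""Panel evaluation statistics.

Simple-matching dissimilarity with binning and top-pair reports, unweighted
neighbor joining, genotype PCA, distance-based AMOVA with PhiPT and a
permutation test, and pairwise LD r² with the four-bin classification.

AMOVA follows the codominant squared-distance framework: squared distance
between individuals is the summed squared allele-count difference, and the
among/within decomposition yields PhiPT = Va / (Va + Vw), an FST analog
that ignores within-individual variation. Significance comes from
permuting whole individuals across groups with group sizes fixed.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats as sps
from sklearn.base import BaseEstimator

from .containers import MISSING, GenotypeMatrix


# --------------------------------------------------------------------------
# Simple-matching dissimilarity
# --------------------------------------------------------------------------

@dataclass
class DistanceMatrix:
    """Pairwise dissimilarities plus the squared-distance companion.

    ``d`` holds simple-matching dissimilarity in [0, 1]; ``d2`` the summed
    squared allele-count differences (rescaled to the total locus count)
    that AMOVA consumes; ``n_complete`` the pairwise-complete locus counts.
    """

    ids: list[str]
    d: np.ndarray
    d2: np.ndarray
    n_complete: np.ndarray

    def __post_init__(self) -> None:
        n = len(self.ids)
        for a in (self.d, self.d2, self.n_complete):
            if a.shape != (n, n):
                raise ValueError("distance matrix shape mismatch")

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.d, index=self.ids, columns=self.ids)


def simple_matching_dissimilarity(matrix: GenotypeMatrix) -> DistanceMatrix:
    """Simple-matching dissimilarity and squared distances between samples.

    Per locus the number of shared alleles between two dosage codes is
    ``m = 2 - |x_i - x_j|`` (equal homozygotes 2, het vs hom 1, opposite
    homozygotes 0, het vs het 2); the dissimilarity is ``1 - mean(m/2)``
    over pairwise-complete loci. The squared distance is
    ``sum((x_i - x_j)^2)`` over complete loci, rescaled by
    ``L_total / L_complete`` so pairs with different missingness stay
    comparable.
    """
    X = matrix.dosage.astype(float)
    X[matrix.dosage == MISSING] = np.nan
    n, L = X.shape
    if n < 2:
        raise ValueError("need at least 2 samples")
    d = np.zeros((n, n))
    d2 = np.zeros((n, n))
    ncomp = np.zeros((n, n), dtype=int)
    np.fill_diagonal(ncomp, L)
    for i in range(n - 1):
        diff = np.abs(X[i] - X[i + 1 :])  # (n-i-1, L) with NaN at incomplete loci
        complete = ~np.isnan(diff)
        cnt = complete.sum(axis=1)
        with np.errstate(invalid="ignore"):
            dij = np.nansum(diff, axis=1) / (2.0 * cnt)
            d2ij = np.nansum(diff**2, axis=1) * (L / np.maximum(cnt, 1))
        dij = np.where(cnt > 0, dij, np.nan)
        d2ij = np.where(cnt > 0, d2ij, np.nan)
        d[i, i + 1 :] = d[i + 1 :, i] = dij
        d2[i, i + 1 :] = d2[i + 1 :, i] = d2ij
        ncomp[i, i + 1 :] = ncomp[i + 1 :, i] = cnt
    if np.isnan(d[np.triu_indices(n, 1)]).any():
        warnings.warn("some sample pairs share zero complete loci; distances missing")
    return DistanceMatrix(list(matrix.samples), d, d2, ncomp)


def classify_dissimilarity(d: float) -> str:
    """low [0, 0.25], medium (0.25, 0.50], high (0.50, 1] (boundaries to
    the lower bin)."""
    if not 0.0 <= d <= 1.0:
        raise ValueError(f"dissimilarity out of [0,1]: {d}")
    if d <= 0.25:
        return "low"
    if d <= 0.50:
        return "medium"
    return "high"


def top_dissimilar_pairs(
    dist: DistanceMatrix,
    groups: dict[str, str],
    mode: str = "between_groups",
    threshold: float = 0.5,
    n: int | None = 20,
) -> pd.DataFrame:
    """Ranked pairs with d > threshold, within or between groups.

    Ties in d break lexicographically on the (sample, sample) id pair.
    """
    if mode not in ("within_group", "between_groups"):
        raise ValueError(f"unknown mode {mode!r}")
    rows = []
    ids = dist.ids
    for i in range(len(ids) - 1):
        for j in range(i + 1, len(ids)):
            gi, gj = groups.get(ids[i]), groups.get(ids[j])
            if gi is None or gj is None:
                continue
            same = gi == gj
            if (mode == "within_group") != same:
                continue
            dij = dist.d[i, j]
            if np.isnan(dij) or dij <= threshold:
                continue
            a, b = sorted((ids[i], ids[j]))
            rows.append(
                {
                    "sample_1": a,
                    "sample_2": b,
                    "group_1": groups[a],
                    "group_2": groups[b],
                    "dissimilarity": dij,
                    "bin": classify_dissimilarity(dij),
                }
            )
    out = pd.DataFrame(
        rows,
        columns=["sample_1", "sample_2", "group_1", "group_2", "dissimilarity", "bin"],
    )
    out = out.sort_values(
        ["dissimilarity", "sample_1", "sample_2"],
        ascending=[False, True, True],
        kind="stable",
    ).reset_index(drop=True)
    return out.head(n) if n is not None else out


# --------------------------------------------------------------------------
# Neighbor joining
# --------------------------------------------------------------------------

def nj_tree(dist: DistanceMatrix) -> str:
    """Unweighted (Saitou–Nei) neighbor joining; returns unrooted Newick
    with branch lengths, negative branch lengths clamped to zero."""
    import skbio

    if len(dist.ids) < 3:
        raise ValueError("neighbor joining needs at least 3 samples")
    tri = np.isnan(dist.d[np.triu_indices(len(dist.ids), 1)])
    if tri.any():
        i, j = np.argwhere(np.isnan(np.triu(dist.d, 1)))[0]
        raise ValueError(
            f"missing pairwise distance between {dist.ids[i]} and {dist.ids[j]}"
        )
    dm = skbio.DistanceMatrix(dist.d, ids=dist.ids)
    tree = skbio.tree.nj(dm)
    for node in tree.traverse():
        if node.length is not None and node.length < 0:
            node.length = 0.0
    return str(tree).strip()


# --------------------------------------------------------------------------
# PCA
# --------------------------------------------------------------------------

@dataclass
class PcaResult:
    eigenvalues: np.ndarray
    variance_fractions: np.ndarray
    scores: np.ndarray  # samples x components
    sample_ids: list[str]

    def to_dict(self) -> dict:
        return {
            "eigenvalues": self.eigenvalues.tolist(),
            "variance_fractions": self.variance_fractions.tolist(),
            "cumulative_fraction": float(self.variance_fractions.sum()),
            "samples": self.sample_ids,
            "scores": self.scores.tolist(),
        }


class GenotypePCA(BaseEstimator):
    """PCA on frequency-standardised dosages, GRM-eigendecomposition style.

    Each marker is centred at twice its ALT frequency and scaled by
    sqrt(2p(1-p)); missing dosages are mean-imputed per marker (zero after
    centring). The sample-by-sample covariance is eigendecomposed and unit
    eigenvectors are reported as sample scores, with per-component variance
    fractions relative to the full spectrum.
    """

    def __init__(self, n_components: int = 15):
        self.n_components = n_components

    def fit(self, X: GenotypeMatrix, y=None) -> "GenotypePCA":
        D = X.dosage.astype(float)
        D[X.dosage == MISSING] = np.nan
        with warnings.catch_warnings():
            warnings.simplefilter("ignore", RuntimeWarning)
            p = np.nanmean(D, axis=0) / 2.0
        keep = np.isfinite(p) & (p > 0) & (p < 1)
        D, p = D[:, keep], p[keep]
        if D.shape[1] == 0:
            raise ValueError("no polymorphic markers for PCA")
        Z = (D - 2 * p) / np.sqrt(2 * p * (1 - p))
        Z[np.isnan(Z)] = 0.0  # mean imputation after centring
        n = Z.shape[0]
        K = Z @ Z.T / Z.shape[1]
        evals, evecs = np.linalg.eigh(K)
        order = np.argsort(evals)[::-1]
        evals, evecs = evals[order], evecs[:, order]
        evals = np.clip(evals, 0.0, None)
        k = self.n_components
        if k > n - 1:
            warnings.warn(
                f"n_components {k} > samples-1 ({n - 1}); capping"
            )
            k = n - 1
        total = evals.sum()
        self.n_markers_used_ = int(Z.shape[1])
        self.eigenvalues_ = evals[:k]
        self.explained_variance_ratio_ = (
            evals[:k] / total if total > 0 else np.zeros(k)
        )
        self.scores_ = evecs[:, :k]
        self.sample_ids_ = list(X.samples)
        return self

    def transform(self, X: GenotypeMatrix) -> np.ndarray:
        if X.samples != self.sample_ids_:
            raise ValueError("GenotypePCA scores are defined for the fitted samples")
        return self.scores_

    def fit_transform(self, X: GenotypeMatrix, y=None) -> np.ndarray:
        return self.fit(X).transform(X)


def pca(matrix: GenotypeMatrix, n_components: int = 15) -> PcaResult:
    est = GenotypePCA(n_components=n_components).fit(matrix)
    return PcaResult(
        eigenvalues=est.eigenvalues_,
        variance_fractions=est.explained_variance_ratio_,
        scores=est.scores_,
        sample_ids=est.sample_ids_,
    )


# --------------------------------------------------------------------------
# AMOVA / PhiPT
# --------------------------------------------------------------------------

@dataclass
class AmovaResult:
    k: int
    n_g: list[int]
    df_among: int
    df_within: int
    ss_among: float
    ss_within: float
    ss_total: float
    ms_among: float
    ms_within: float
    n0: float
    va: float
    vw: float
    phi_pt: float
    pct_among: float
    pct_within: float
    p_perm: float | None = None
    n_perm: int = 0

    def to_frame(self) -> pd.DataFrame:
        """Table shaped Source / df / SS / MS / Est. Var. / Variance % /
        PhiPT / p."""
        return pd.DataFrame(
            [
                {
                    "Source": "Among groups",
                    "df": self.df_among,
                    "SS": self.ss_among,
                    "MS": self.ms_among,
                    "Est.Var": self.va,
                    "Variance_pct": self.pct_among,
                    "PhiPT": self.phi_pt,
                    "p": self.p_perm,
                },
                {
                    "Source": "Within groups",
                    "df": self.df_within,
                    "SS": self.ss_within,
                    "MS": self.ms_within,
                    "Est.Var": self.vw,
                    "Variance_pct": self.pct_within,
                    "PhiPT": None,
                    "p": None,
                },
                {
                    "Source": "Total",
                    "df": self.df_among + self.df_within,
                    "SS": self.ss_total,
                    "MS": None,
                    "Est.Var": self.va + self.vw,
                    "Variance_pct": 100.0,
                    "PhiPT": None,
                    "p": None,
                },
            ]
        )


def _complete_amova(
    ss_among: float,
    ss_within: float,
    group_sizes: list[int],
) -> dict:
    k = len(group_sizes)
    if k < 2:
        raise ValueError("AMOVA needs at least 2 groups")
    if any(n <= 0 for n in group_sizes):
        raise ValueError("every group must be non-empty")
    if ss_among < 0 or ss_within < 0:
        raise ValueError("sums of squares must be non-negative")
    N = sum(group_sizes)
    df_among = k - 1
    df_within = N - k
    if df_within <= 0:
        raise ValueError("non-positive within-group degrees of freedom")
    ms_among = ss_among / df_among
    ms_within = ss_within / df_within
    n0 = (N - sum(n * n for n in group_sizes) / N) / (k - 1)
    va = (ms_among - ms_within) / n0
    vw = ms_within
    total = va + vw
    if total == 0:
        raise ValueError("zero total variance; PhiPT undefined")
    phi = va / total
    return dict(
        k=k,
        n_g=list(group_sizes),
        df_among=df_among,
        df_within=df_within,
        ss_among=ss_among,
        ss_within=ss_within,
        ss_total=ss_among + ss_within,
        ms_among=ms_among,
        ms_within=ms_within,
        n0=n0,
        va=va,
        vw=vw,
        phi_pt=phi,
        pct_among=100.0 * va / total,
        pct_within=100.0 * vw / total,
    )


def amova_from_ss(
    ss_among: float, ss_within: float, group_sizes: list[int]
) -> AmovaResult:
    """Complete the two-level AMOVA decomposition from sums of squares
    alone (no permutation test). Negative Va is reported as computed."""
    return AmovaResult(**_complete_amova(ss_among, ss_within, group_sizes))


def _ss_decomposition(
    d2: np.ndarray, labels: np.ndarray, groups: list
) -> tuple[float, float]:
    N = d2.shape[0]
    iu = np.triu_indices(N, 1)
    ss_total = d2[iu].sum() / N
    ss_within = 0.0
    for g in groups:
        idx = np.flatnonzero(labels == g)
        sub = d2[np.ix_(idx, idx)]
        ss_within += np.triu(sub, 1).sum() / len(idx)
    return ss_total, ss_within


def amova_from_distances(
    d2: np.ndarray | DistanceMatrix,
    groups: list[str],
    n_perm: int = 999,
    seed: int = 0,
) -> AmovaResult:
    """Distance-based AMOVA with a whole-individual permutation test.

    ``SS_total = (1/N) sum_{i<j} d2_ij`` and ``SS_within`` sums the same
    quantity per group with its own size; PhiPT derives from the variance
    components and ``p = (1 + #{perm PhiPT >= observed}) / (n_perm + 1)``.
    """
    if isinstance(d2, DistanceMatrix):
        d2 = d2.d2
    d2 = np.asarray(d2, dtype=float)
    if np.isnan(d2).any():
        raise ValueError("squared-distance matrix contains missing entries")
    labels = np.asarray(groups)
    if labels.shape[0] != d2.shape[0]:
        raise ValueError("group labels must align with the distance matrix")
    uniq = sorted(set(labels.tolist()))
    sizes = [int((labels == g).sum()) for g in uniq]
    ss_total, ss_within = _ss_decomposition(d2, labels, uniq)
    res = _complete_amova(ss_total - ss_within, ss_within, sizes)

    p_perm = None
    if n_perm > 0:
        rng = np.random.default_rng(seed)
        phi_obs = res["phi_pt"]
        hits = 0
        for _ in range(n_perm):
            perm = rng.permutation(labels)
            st, sw = _ss_decomposition(d2, perm, uniq)
            try:
                phi_p = _complete_amova(st - sw, sw, sizes)["phi_pt"]
            except ValueError:
                continue
            if phi_p >= phi_obs:
                hits += 1
        p_perm = (1 + hits) / (n_perm + 1)
    return AmovaResult(**res, p_perm=p_perm, n_perm=n_perm)


# --------------------------------------------------------------------------
# Linkage disequilibrium
# --------------------------------------------------------------------------

def ld_filter_markers(
    matrix: GenotypeMatrix, max_het: float = 0.15, max_missing: float = 0.20
) -> GenotypeMatrix:
    """Inclusion filter for LD analysis: Ho <= max_het and missing fraction
    <= max_missing; no MAF floor. Monomorphic markers pass here and are
    skipped at the r² stage (zero variance)."""
    from . import stats as mstats

    keep = []
    for j in range(matrix.n_markers):
        col = matrix.column(j)
        cr = mstats.call_rate(col)
        if 1.0 - cr > max_missing:
            continue
        if cr == 0.0:
            continue
        if mstats.observed_het(col) > max_het:
            continue
        keep.append(j)
    return matrix.subset_markers(keep)


def pairwise_r2(x: np.ndarray, y: np.ndarray) -> float | None:
    """Squared Pearson correlation of two dosage vectors over
    pairwise-complete samples; None when undefined (zero variance or < 2
    complete samples)."""
    mask = (x != MISSING) & (y != MISSING)
    if mask.sum() < 2:
        return None
    xs, ys = x[mask].astype(float), y[mask].astype(float)
    if xs.std() == 0 or ys.std() == 0:
        return None
    r = np.corrcoef(xs, ys)[0, 1]
    return float(r * r)


def ld_r2(matrix: GenotypeMatrix, scope: str = "chrom") -> pd.DataFrame:
    """All pairwise dosage r² values with two-sided p-values.

    ``scope='chrom'`` (default) restricts to same-chromosome pairs;
    ``scope='genome'`` computes every pair. Zero-variance pairs are skipped
    and counted in the ``skipped`` attribute of the returned frame.
    """
    if matrix.n_markers < 2:
        raise ValueError("need at least 2 markers for LD")
    rows = []
    skipped = 0
    idx_by_chrom: dict[str, list[int]] = {}
    if scope == "chrom":
        for j, m in enumerate(matrix.markers):
            idx_by_chrom.setdefault(m.chrom, []).append(j)
    elif scope == "genome":
        idx_by_chrom = {"*": list(range(matrix.n_markers))}
    else:
        raise ValueError(f"unknown scope {scope!r}")
    for _, idx in sorted(idx_by_chrom.items()):
        for a in range(len(idx) - 1):
            for b in range(a + 1, len(idx)):
                j1, j2 = idx[a], idx[b]
                m1, m2 = matrix.markers[j1], matrix.markers[j2]
                x, y = matrix.column(j1), matrix.column(j2)
                mask = (x != MISSING) & (y != MISSING)
                if mask.sum() < 2:
                    skipped += 1
                    continue
                xs = x[mask].astype(float)
                ys = y[mask].astype(float)
                if xs.std() == 0 or ys.std() == 0:
                    skipped += 1
                    continue
                r, p = sps.pearsonr(xs, ys)
                rows.append(
                    {
                        "marker_1": m1.id,
                        "marker_2": m2.id,
                        "chrom": m1.chrom if m1.chrom == m2.chrom else "*",
                        "bp_distance": abs(m1.pos - m2.pos)
                        if m1.chrom == m2.chrom
                        else np.nan,
                        "r2": float(r * r),
                        "p_value": float(p),
                    }
                )
    out = pd.DataFrame(
        rows, columns=["marker_1", "marker_2", "chrom", "bp_distance", "r2", "p_value"]
    )
    out.attrs["skipped"] = skipped
    return out


LD_BINS = ("very_low", "low", "moderate", "high")


def classify_ld(
    pairs: pd.DataFrame, edges: tuple[float, float, float] = (0.10, 0.50, 0.90)
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Bin r² values: very_low [0, e1), low [e1, e2), moderate [e2, e3),
    high [e3, 1]; returns the annotated pairs plus per-chromosome bin
    counts with bp-span statistics."""
    e1, e2, e3 = edges
    if not 0.0 < e1 < e2 < e3 <= 1.0:
        raise ValueError(f"edges must be strictly increasing in (0,1]: {edges}")
    pairs = pairs.copy()
    bins = np.select(
        [pairs.r2 < e1, pairs.r2 < e2, pairs.r2 < e3],
        ["very_low", "low", "moderate"],
        default="high",
    )
    pairs["bin"] = bins
    grouped = pairs.groupby(["chrom", "bin"], observed=False)
    summary = grouped.agg(
        n_pairs=("r2", "size"),
        min_bp=("bp_distance", "min"),
        max_bp=("bp_distance", "max"),
    ).reset_index()
    genome = (
        pairs.groupby("bin")
        .agg(
            n_pairs=("r2", "size"),
            min_bp=("bp_distance", "min"),
            max_bp=("bp_distance", "max"),
        )
        .reset_index()
    )
    genome.insert(0, "chrom", "genome")
    summary = pd.concat([summary, genome], ignore_index=True)
    return pairs, summary
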