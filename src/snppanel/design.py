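"""The in-silico marker-mining cascade.

Each stage is a scikit-learn-style *marker selector*: ``fit`` computes a
boolean ``support_`` over the columns of a
:class:`~snppanel.containers.GenotypeMatrix` together with per-marker drop
reasons, and ``transform`` returns the column-subsetted matrix. Stages
compose sequentially (they also work inside ``sklearn.pipeline.Pipeline``,
since the matrix container passes through opaquely) and every stage appends
a :class:`FilterStage` record so the full cascade leaves an auditable
:class:`FilterTrace`.

Cascade order: site quality (call rate / MAF / biallelic) -> probe
specificity (unique exact match in the reference) -> flanking-variant
window -> flanking SSR -> exonic restriction -> information-maximising
subset selection -> LD / redundancy pruning -> panel assembly.
"""

from __future__ import annotations

import warnings
from collections import Counter
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from sklearn.base import BaseEstimator

from .containers import MISSING, GenotypeMatrix, MarkerRecord, PanelManifest
from . import stats as mstats


# --------------------------------------------------------------------------
# Trace bookkeeping
# --------------------------------------------------------------------------

@dataclass
class FilterStage:
    stage: str
    n_in: int
    n_out: int
    reasons: Counter = field(default_factory=Counter)


@dataclass
class FilterTrace:
    stages: list[FilterStage] = field(default_factory=list)

    def add(self, stage: FilterStage) -> None:
        if self.stages and stage.n_in != self.stages[-1].n_out:
            raise ValueError(
                f"stage {stage.stage!r}: n_in {stage.n_in} != previous n_out "
                f"{self.stages[-1].n_out}"
            )
        if stage.n_out > stage.n_in:
            raise ValueError(f"stage {stage.stage!r}: n_out > n_in")
        self.stages.append(stage)

    def to_frame(self) -> pd.DataFrame:
        import json

        return pd.DataFrame(
            [
                {
                    "stage": s.stage,
                    "markers_in": s.n_in,
                    "markers_out": s.n_out,
                    "reasons": json.dumps(dict(sorted(s.reasons.items()))),
                }
                for s in self.stages
            ]
        )


class _MarkerSelector(BaseEstimator):
    """Shared fit/transform plumbing; subclasses implement ``_evaluate``.

    ``_evaluate`` returns ``(support, reasons)`` where ``support`` is a
    boolean mask over markers and ``reasons`` maps dropped marker index ->
    reason string.
    """

    stage_name: str = "selector"

    def fit(self, X: GenotypeMatrix, y=None) -> "_MarkerSelector":
        support, reasons = self._evaluate(X)
        self.support_ = np.asarray(support, dtype=bool)
        self.reasons_ = dict(reasons)
        self.n_features_in_ = X.n_markers
        self.trace_stage_ = FilterStage(
            self.stage_name,
            X.n_markers,
            int(self.support_.sum()),
            Counter(self.reasons_.values()),
        )
        return self

    def transform(self, X: GenotypeMatrix) -> GenotypeMatrix:
        if not hasattr(self, "support_"):
            raise RuntimeError("selector not fitted")
        if X.n_markers != self.n_features_in_:
            raise ValueError("marker count changed since fit")
        return X.subset_markers(np.flatnonzero(self.support_))

    def fit_transform(self, X: GenotypeMatrix, y=None) -> GenotypeMatrix:
        return self.fit(X).transform(X)

    def get_support(self) -> np.ndarray:
        return self.support_

    def _evaluate(self, X: GenotypeMatrix):  # pragma: no cover - abstract
        raise NotImplementedError


# --------------------------------------------------------------------------
# Stage 1: site quality
# --------------------------------------------------------------------------

class SiteQualityFilter(_MarkerSelector):
    """Retain biallelic markers with call_rate >= min_call_rate and
    maf >= min_maf (both bounds inclusive)."""

    stage_name = "site_quality"

    def __init__(self, min_call_rate: float = 0.90, min_maf: float = 0.01):
        self.min_call_rate = min_call_rate
        self.min_maf = min_maf

    def _evaluate(self, X: GenotypeMatrix):
        support = np.ones(X.n_markers, dtype=bool)
        reasons: dict[int, str] = {}
        for j, m in enumerate(X.markers):
            if m.multiallelic:
                support[j], reasons[j] = False, "multiallelic"
                continue
            col = X.column(j)
            if mstats.call_rate(col) < self.min_call_rate:
                support[j], reasons[j] = False, "low_call_rate"
                continue
            try:
                _, maf = mstats.allele_freq_and_maf(col)
            except mstats.UndefinedStatisticError:
                support[j], reasons[j] = False, "low_call_rate"
                continue
            if maf < self.min_maf:
                support[j], reasons[j] = False, "low_maf"
        return support, reasons


# --------------------------------------------------------------------------
# Stage 2: probe specificity
# --------------------------------------------------------------------------

_RC = str.maketrans("ACGTN", "TGCAN")


def reverse_complement(seq: str) -> str:
    return seq.translate(_RC)[::-1]


def _hit_positions(haystacks: dict[str, str], needle: str) -> set[tuple[str, int]]:
    """All (chrom, start) occurrences of needle, overlapping matches included."""
    hits: set[tuple[str, int]] = set()
    for chrom, seq in haystacks.items():
        start = seq.find(needle)
        while start != -1:
            hits.add((chrom, start))
            start = seq.find(needle, start + 1)
    return hits


def check_specificity(
    marker: MarkerRecord, reference: dict[str, str], min_probe_len: int = 30
) -> bool:
    """True iff flank+ref+flank maps exactly once (either strand, zero
    mismatches) in the reference."""
    probe = marker.probe
    if probe is None:
        raise ValueError(f"marker {marker.id}: flanks not populated")
    if len(probe) < min_probe_len:
        return False
    # a site matched on both strands (palindrome) is still one location
    hits = _hit_positions(reference, probe) | _hit_positions(
        reference, reverse_complement(probe)
    )
    return len(hits) == 1


class SpecificityFilter(_MarkerSelector):
    """Drop probes that map zero or multiple times in the reference, and
    probes truncated below the minimum length."""

    stage_name = "specificity"

    def __init__(self, reference: dict[str, str] | None = None, min_probe_len: int = 30):
        self.reference = reference
        self.min_probe_len = min_probe_len

    def _evaluate(self, X: GenotypeMatrix):
        if self.reference is None:
            raise ValueError("SpecificityFilter needs a reference")
        ref = {c: s.upper() for c, s in self.reference.items()}
        support = np.ones(X.n_markers, dtype=bool)
        reasons: dict[int, str] = {}
        for j, m in enumerate(X.markers):
            probe = m.probe
            if probe is None or len(probe) < self.min_probe_len:
                support[j], reasons[j] = False, "short_flank"
            elif not check_specificity(m, ref, self.min_probe_len):
                support[j], reasons[j] = False, "nonunique"
        return support, reasons


# --------------------------------------------------------------------------
# Stage 3: flanking-variant window
# --------------------------------------------------------------------------

class FlankingVariantFilter(_MarkerSelector):
    """Drop candidates with any *other* raw variant within +-window_bp.

    ``all_variants`` must cover every site in the source VCF, not only the
    surviving candidates; both members of a close pair are dropped.
    """

    stage_name = "flanking_variants"

    def __init__(
        self,
        all_variants: list[tuple[str, int]] | None = None,
        window_bp: int = 50,
    ):
        self.all_variants = all_variants
        self.window_bp = window_bp

    def _evaluate(self, X: GenotypeMatrix):
        if self.all_variants is None:
            raise ValueError("FlankingVariantFilter needs the raw variant list")
        by_chrom: dict[str, np.ndarray] = {}
        for chrom, pos in self.all_variants:
            by_chrom.setdefault(chrom, []).append(pos)  # type: ignore[arg-type]
        by_chrom = {c: np.array(sorted(p)) for c, p in by_chrom.items()}
        support = np.ones(X.n_markers, dtype=bool)
        reasons: dict[int, str] = {}
        for j, m in enumerate(X.markers):
            pos = by_chrom.get(m.chrom)
            if pos is None:
                continue
            lo = np.searchsorted(pos, m.pos - self.window_bp, side="left")
            hi = np.searchsorted(pos, m.pos + self.window_bp, side="right")
            # exclude the candidate's own record
            n_near = hi - lo - int(np.any(pos[lo:hi] == m.pos))
            if n_near > 0:
                support[j], reasons[j] = False, "flanking_variant"
        return support, reasons


# --------------------------------------------------------------------------
# Stage 4: flanking SSRs
# --------------------------------------------------------------------------

def detect_ssr(
    sequence: str,
    min_unit: int = 1,
    max_unit: int = 6,
    min_tract_bp: int = 12,
) -> list[tuple[str, int, int, int]]:
    """Maximal perfect tandem tracts (microsatellites) in a sequence.

    Returns ``(motif, unit_len, tract_start, tract_len)`` for every maximal
    run of a primitive motif of length ``min_unit..max_unit`` spanning at
    least ``min_tract_bp`` and at least two full units. ``tract_start`` is
    0-based. 'N' never matches.
    """
    seq = sequence.upper()
    n = len(seq)
    found: list[tuple[str, int, int, int]] = []
    for u in range(min_unit, max_unit + 1):
        i = 0
        while i + u <= n:
            # left-maximality: previous base must break the period
            if i > 0 and i - 1 + u < n and seq[i - 1] == seq[i - 1 + u] and seq[i - 1] != "N":
                i += 1
                continue
            j = i + u
            while j < n and seq[j] == seq[j - u] and seq[j] != "N":
                j += 1
            tract_len = j - i
            motif = seq[i : i + u]
            if (
                tract_len >= max(min_tract_bp, 2 * u)
                and "N" not in motif
                and _is_primitive(motif)
            ):
                found.append((motif, u, i, tract_len))
            i += 1
    return sorted(found, key=lambda t: (t[2], t[1]))


def _is_primitive(motif: str) -> bool:
    """True if the motif is not itself a tandem of a shorter unit."""
    u = len(motif)
    for d in range(1, u):
        if u % d == 0 and motif == motif[:d] * (u // d):
            return False
    return True


class SSRFilter(_MarkerSelector):
    """Drop markers with a microsatellite tract in either flank — tandem
    repeats destabilise targeted-amplicon probes."""

    stage_name = "flanking_ssr"

    def __init__(self, min_unit: int = 1, max_unit: int = 6, min_tract_bp: int = 12):
        self.min_unit = min_unit
        self.max_unit = max_unit
        self.min_tract_bp = min_tract_bp

    def _evaluate(self, X: GenotypeMatrix):
        support = np.ones(X.n_markers, dtype=bool)
        reasons: dict[int, str] = {}
        for j, m in enumerate(X.markers):
            for flank in (m.left_flank, m.right_flank):
                if flank and detect_ssr(
                    flank, self.min_unit, self.max_unit, self.min_tract_bp
                ):
                    support[j], reasons[j] = False, "flanking_ssr"
                    break
        return support, reasons


# --------------------------------------------------------------------------
# Stage 5: exonic restriction
# --------------------------------------------------------------------------

class ExonFilter(_MarkerSelector):
    """Keep exonic markers only; unannotated markers are dropped and
    counted separately."""

    stage_name = "exonic"

    def _evaluate(self, X: GenotypeMatrix):
        support = np.zeros(X.n_markers, dtype=bool)
        reasons: dict[int, str] = {}
        for j, m in enumerate(X.markers):
            if m.region == "exon":
                support[j] = True
            elif m.region == "unknown":
                reasons[j] = "unannotated"
            else:
                reasons[j] = f"non_exonic_{m.region}"
        return support, reasons


# --------------------------------------------------------------------------
# Stage 6: information-maximising subset selection
# --------------------------------------------------------------------------

class InformativeSubsetSelector(_MarkerSelector):
    """Greedy selection maximising summed PIC under per-chromosome quotas
    and a minimum inter-marker spacing.

    Quotas are proportional to per-chromosome candidate counts (largest
    remainder) or disabled (``quota_policy='none'``). The greedy walk is
    deterministic given ``seed``: the seed only permutes candidates before a
    stable sort by descending PIC, so equal-PIC ties resolve differently per
    seed. An exhausted chromosome relaxes its quota to the others with a
    warning, never a silent shortfall.
    """

    stage_name = "informative_subset"

    def __init__(
        self,
        target_n: int = 6000,
        quota_policy: str = "proportional",
        min_spacing_bp: int = 0,
        seed: int = 0,
    ):
        self.target_n = target_n
        self.quota_policy = quota_policy
        self.min_spacing_bp = min_spacing_bp
        self.seed = seed

    def _evaluate(self, X: GenotypeMatrix):
        if self.target_n > X.n_markers:
            raise ValueError(
                f"target_n {self.target_n} exceeds candidate count {X.n_markers}"
            )
        pics = np.array(
            [
                mstats.pic(mstats.allele_freq_and_maf(X.column(j))[0])
                for j in range(X.n_markers)
            ]
        )
        chroms = [m.chrom for m in X.markers]
        uniq = sorted(set(chroms))
        counts = {c: chroms.count(c) for c in uniq}

        if self.quota_policy == "proportional" and len(uniq) > 1:
            quota = _largest_remainder(
                {c: counts[c] for c in uniq}, self.target_n
            )
        else:
            quota = {c: self.target_n for c in uniq}  # effectively unconstrained

        rng = np.random.default_rng(self.seed)
        order = rng.permutation(X.n_markers)
        order = order[np.argsort(-pics[order], kind="stable")]

        chosen: list[int] = []
        taken_per_chrom: Counter = Counter()
        pos_per_chrom: dict[str, list[int]] = {c: [] for c in uniq}

        def admissible(j: int) -> bool:
            c = chroms[j]
            if taken_per_chrom[c] >= quota[c]:
                return False
            if self.min_spacing_bp > 0:
                p = X.markers[j].pos
                if any(
                    abs(p - q) < self.min_spacing_bp for q in pos_per_chrom[c]
                ):
                    return False
            return True

        remaining = list(order)
        while len(chosen) < self.target_n and remaining:
            progressed = False
            nxt = []
            for j in remaining:
                if len(chosen) >= self.target_n:
                    break
                if admissible(j):
                    chosen.append(j)
                    c = chroms[j]
                    taken_per_chrom[c] += 1
                    pos_per_chrom[c].append(X.markers[j].pos)
                    progressed = True
                else:
                    nxt.append(j)
            remaining = nxt
            if not progressed:
                if len(chosen) < self.target_n and remaining:
                    warnings.warn(
                        "per-chromosome quota infeasible; relaxing quotas"
                    )
                    for c in quota:
                        quota[c] = self.target_n
                    # spacing still enforced; a second stall means genuine
                    # infeasibility and we stop with what is attainable
                    progressed2 = False
                    nxt2 = []
                    for j in remaining:
                        if len(chosen) >= self.target_n:
                            break
                        if admissible(j):
                            chosen.append(j)
                            taken_per_chrom[chroms[j]] += 1
                            pos_per_chrom[chroms[j]].append(X.markers[j].pos)
                            progressed2 = True
                        else:
                            nxt2.append(j)
                    remaining = nxt2
                    if not progressed2:
                        break
                else:
                    break

        support = np.zeros(X.n_markers, dtype=bool)
        support[chosen] = True
        reasons = {
            j: "not_selected" for j in range(X.n_markers) if not support[j]
        }
        self.mean_pic_ = float(pics[chosen].mean()) if chosen else float("nan")
        return support, reasons


def _largest_remainder(weights: dict[str, int], total: int) -> dict[str, int]:
    """Integer apportionment of ``total`` proportional to weights; never
    allocates more than a chromosome's candidate count."""
    wsum = sum(weights.values())
    raw = {c: total * w / wsum for c, w in weights.items()}
    alloc = {c: min(int(raw[c]), weights[c]) for c in weights}
    while sum(alloc.values()) < min(total, wsum):
        # give the next seat to the largest remainder with capacity left
        best = max(
            (c for c in weights if alloc[c] < weights[c]),
            key=lambda c: (raw[c] - alloc[c], c),
        )
        alloc[best] += 1
    return alloc


# --------------------------------------------------------------------------
# Stage 7: LD + redundancy pruning
# --------------------------------------------------------------------------

class LDRedundancyPruner(_MarkerSelector):
    """Remove duplicate genotype columns, then break high-LD pairs, then
    trim to ``final_n`` by dropping lowest-PIC markers.

    High-LD resolution: for each same-chromosome pair with r² >=
    ``r2_threshold`` the lower-PIC member is dropped (tie: the larger
    position). The final trim drops globally lowest-PIC markers, always
    from the chromosome currently furthest above its proportional share, so
    the panel stays balanced.
    """

    stage_name = "ld_redundancy"

    def __init__(self, r2_threshold: float = 0.90, final_n: int | None = 2000):
        self.r2_threshold = r2_threshold
        self.final_n = final_n

    def _evaluate(self, X: GenotypeMatrix):
        support = np.ones(X.n_markers, dtype=bool)
        reasons: dict[int, str] = {}

        # exact duplicate columns (missingness pattern included)
        seen: dict[bytes, int] = {}
        for j in range(X.n_markers):
            key = X.column(j).tobytes()
            if key in seen:
                support[j], reasons[j] = False, "duplicate_column"
            else:
                seen[key] = j

        pics = np.full(X.n_markers, np.nan)
        for j in range(X.n_markers):
            try:
                pics[j] = mstats.pic(mstats.allele_freq_and_maf(X.column(j))[0])
            except mstats.UndefinedStatisticError:
                pics[j] = 0.0

        # high-LD pairs within chromosomes, processed in genome order
        from .popgen import pairwise_r2

        alive = np.flatnonzero(support)
        by_chrom: dict[str, list[int]] = {}
        for j in alive:
            by_chrom.setdefault(X.markers[j].chrom, []).append(j)
        for chrom, idx in sorted(by_chrom.items()):
            idx = sorted(idx, key=lambda j: X.markers[j].pos)
            for a_i in range(len(idx)):
                j1 = idx[a_i]
                if not support[j1]:
                    continue
                for b_i in range(a_i + 1, len(idx)):
                    j2 = idx[b_i]
                    if not support[j2]:
                        continue
                    r2 = pairwise_r2(X.column(j1), X.column(j2))
                    if r2 is not None and r2 >= self.r2_threshold:
                        if pics[j1] > pics[j2]:
                            drop = j2
                        elif pics[j1] < pics[j2]:
                            drop = j1
                        else:  # tie -> larger position goes
                            drop = j1 if X.markers[j1].pos > X.markers[j2].pos else j2
                        support[drop], reasons[drop] = False, "high_ld"
                        if drop == j1:
                            break

        if self.final_n is not None:
            alive = [int(j) for j in np.flatnonzero(support)]
            if self.final_n > len(alive):
                warnings.warn(
                    f"final_n {self.final_n} exceeds surviving markers "
                    f"({len(alive)}); keeping all"
                )
            chrom_of = {j: X.markers[j].chrom for j in alive}
            total_counts = Counter(chrom_of.values())
            n_total = len(alive)
            while len(alive) > self.final_n:
                live_counts = Counter(chrom_of[j] for j in alive)
                # chromosome most above its proportional share loses first
                excess = {
                    c: live_counts[c] - self.final_n * total_counts[c] / n_total
                    for c in live_counts
                }
                worst = max(sorted(excess), key=lambda c: excess[c])
                drop = min(
                    (j for j in alive if chrom_of[j] == worst),
                    key=lambda j: (pics[j], -X.markers[j].pos),
                )
                alive.remove(drop)
                support[drop], reasons[drop] = False, "low_pic_trim"
        return support, reasons


# --------------------------------------------------------------------------
# Panel assembly + cascade driver
# --------------------------------------------------------------------------

def assemble_panel(
    set_i: GenotypeMatrix, set_ii: GenotypeMatrix
) -> tuple[PanelManifest, dict]:
    """Union of the two selections keyed by (chrom, pos).

    Loci shared between the sets are collapsed to one row with
    ``source_set="I,II"``; conflicting ref/alt at the same locus is a
    validation error. Returns the manifest plus a count report (rows in
    each set, shared loci, combined total before/after dedup).
    """
    rows: dict[tuple[str, int], dict] = {}
    for label, sel in (("I", set_i), ("II", set_ii)):
        for j, m in enumerate(sel.markers):
            p, _ = mstats.allele_freq_and_maf(sel.column(j))
            key = (m.chrom, m.pos)
            if key in rows:
                prev = rows[key]
                if (prev["ref"], prev["alt"]) != (m.ref, m.alt):
                    raise ValueError(
                        f"conflicting alleles at {m.chrom}:{m.pos} between sets"
                    )
                prev["source_set"] = prev["source_set"] + "," + label
            else:
                rows[key] = {
                    "id": m.id,
                    "chrom": m.chrom,
                    "pos": m.pos,
                    "ref": m.ref,
                    "alt": m.alt,
                    "source_set": label,
                    "pic": mstats.pic(p),
                }
    manifest = PanelManifest(pd.DataFrame(list(rows.values())))
    report = {
        "set_I": set_i.n_markers,
        "set_II": set_ii.n_markers,
        "combined_with_duplicates": set_i.n_markers + set_ii.n_markers,
        "unique_loci": len(manifest),
        "shared_loci": set_i.n_markers + set_ii.n_markers - len(manifest),
    }
    return manifest, report


# thin functional wrappers over the selector estimators ---------------------

def filter_site_quality(matrix, min_call_rate=0.90, min_maf=0.01):
    f = SiteQualityFilter(min_call_rate, min_maf).fit(matrix)
    return f.transform(matrix), f.trace_stage_


def filter_flanking_variants(matrix, all_variants, window_bp=50):
    f = FlankingVariantFilter(all_variants, window_bp).fit(matrix)
    return f.transform(matrix), f.trace_stage_


def filter_exonic(matrix):
    f = ExonFilter().fit(matrix)
    return f.transform(matrix), f.trace_stage_


def select_informative_subset(matrix, target_n, quota_policy="proportional",
                              min_spacing_bp=0, seed=0):
    f = InformativeSubsetSelector(target_n, quota_policy, min_spacing_bp, seed)
    f.fit(matrix)
    return f.transform(matrix), f.trace_stage_


def prune_ld_and_redundancy(matrix, r2_threshold=0.90, final_n=None):
    f = LDRedundancyPruner(r2_threshold, final_n).fit(matrix)
    return f.transform(matrix), f.trace_stage_


@dataclass
class DesignConfig:
    """Tunables of the mining cascade (defaults are the standard run)."""

    min_call_rate: float = 0.90
    min_maf: float = 0.01
    window_bp: int = 50
    flank_size: int = 50
    min_probe_len: int = 30
    ssr_min_unit: int = 1
    ssr_max_unit: int = 6
    ssr_min_tract_bp: int = 12
    subset_target: int = 6000
    final_target: int = 2000
    ld_prune_r2: float = 0.90
    quota_policy: str = "proportional"
    min_spacing_bp: int = 0

    def __post_init__(self) -> None:
        for name in ("min_call_rate", "min_maf", "ld_prune_r2"):
            v = getattr(self, name)
            if not 0.0 <= v <= 1.0:
                raise ValueError(f"{name} must be in [0,1], got {v}")
        if self.subset_target < self.final_target:
            raise ValueError("subset_target must be >= final_target")


def run_cascade(
    matrix: GenotypeMatrix,
    reference: dict[str, str],
    all_variants: list[tuple[str, int]],
    config: DesignConfig,
    seed: int = 0,
) -> tuple[GenotypeMatrix, FilterTrace]:
    """Run the full mining cascade on an annotated, flank-populated matrix.

    Selection targets are capped at the surviving candidate count so small
    inputs run end-to-end.
    """
    trace = FilterTrace()
    stages: list[_MarkerSelector] = [
        SiteQualityFilter(config.min_call_rate, config.min_maf),
        SpecificityFilter(reference, config.min_probe_len),
        FlankingVariantFilter(all_variants, config.window_bp),
        SSRFilter(config.ssr_min_unit, config.ssr_max_unit, config.ssr_min_tract_bp),
        ExonFilter(),
    ]
    X = matrix
    for stage in stages:
        X = stage.fit_transform(X)
        trace.add(stage.trace_stage_)

    subset = InformativeSubsetSelector(
        target_n=min(config.subset_target, X.n_markers),
        quota_policy=config.quota_policy,
        min_spacing_bp=config.min_spacing_bp,
        seed=seed,
    )
    X = subset.fit_transform(X)
    trace.add(subset.trace_stage_)

    pruner = LDRedundancyPruner(
        r2_threshold=config.ld_prune_r2,
        final_n=min(config.final_target, X.n_markers),
    )
    X = pruner.fit_transform(X)
    trace.add(pruner.trace_stage_)
    return X, trace
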