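"""Core in-memory containers shared by every module.

Coordinates are 1-based inclusive throughout (VCF convention); BED export
converts to 0-based half-open at the boundary. Genotypes are stored as ALT
allele dosage in {0, 1, 2} with ``MISSING`` (-1) as the sentinel for
no-call; the sentinel never participates in arithmetic.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

#: Reserved dosage code for a missing genotype call (half-missing GTs included).
MISSING: int = -1

REGIONS = ("exon", "intron", "upstream", "downstream", "intergenic", "unknown")


@dataclass
class MarkerRecord:
    """A single SNP locus with optional flank and annotation context."""

    id: str
    chrom: str
    pos: int  # 1-based reference coordinate
    ref: str
    alt: str
    left_flank: str | None = None
    right_flank: str | None = None
    region: str = "unknown"
    multiallelic: bool = False
    flank_truncated: bool = False

    def __post_init__(self) -> None:
        if self.pos < 1:
            raise ValueError(f"marker {self.id}: pos must be >= 1, got {self.pos}")
        if self.ref == self.alt:
            raise ValueError(f"marker {self.id}: ref == alt ({self.ref})")
        if self.region not in REGIONS:
            raise ValueError(f"marker {self.id}: unknown region label {self.region!r}")

    @property
    def probe(self) -> str | None:
        """Flank + ref base + flank, the exact-match specificity probe."""
        if self.left_flank is None or self.right_flank is None:
            return None
        return self.left_flank + self.ref + self.right_flank


class GenotypeMatrix:
    """samples x markers ALT-dosage matrix with group labels.

    Parameters
    ----------
    samples
        Ordered sample identifiers.
    markers
        Ordered :class:`MarkerRecord` list, one per column.
    dosage
        ``(n_samples, n_markers)`` integer array over {0, 1, 2, MISSING}.
    groups
        Optional map sample id -> group label (e.g. ``"B"``/``"R"``).
    """

    def __init__(
        self,
        samples: Sequence[str],
        markers: Sequence[MarkerRecord],
        dosage: np.ndarray,
        groups: Mapping[str, str] | None = None,
    ) -> None:
        dosage = np.asarray(dosage, dtype=np.int16)
        if dosage.shape != (len(samples), len(markers)):
            raise ValueError(
                f"dosage shape {dosage.shape} != (samples={len(samples)}, "
                f"markers={len(markers)})"
            )
        bad = ~np.isin(dosage, (0, 1, 2, MISSING))
        if bad.any():
            raise ValueError(f"dosage contains invalid codes: {np.unique(dosage[bad])}")
        ids = [m.id for m in markers]
        if len(set(ids)) != len(ids):
            raise ValueError("duplicate marker ids")
        self.samples = list(samples)
        self.markers = list(markers)
        self.dosage = dosage
        self.groups = dict(groups) if groups else {}
        unknown = set(self.groups) - set(self.samples)
        if unknown:
            raise ValueError(f"group labels for unknown samples: {sorted(unknown)}")

    # -- basic protocol ----------------------------------------------------
    @property
    def n_samples(self) -> int:
        return len(self.samples)

    @property
    def n_markers(self) -> int:
        return len(self.markers)

    def marker_ids(self) -> list[str]:
        return [m.id for m in self.markers]

    def column(self, j: int) -> np.ndarray:
        return self.dosage[:, j]

    def group_labels(self) -> list[str | None]:
        return [self.groups.get(s) for s in self.samples]

    # -- subsetting --------------------------------------------------------
    def subset_markers(self, index: Iterable[int]) -> "GenotypeMatrix":
        idx = np.asarray(list(index), dtype=int)
        return GenotypeMatrix(
            self.samples,
            [self.markers[j] for j in idx],
            self.dosage[:, idx],
            self.groups,
        )

    def subset_samples(self, index: Iterable[int]) -> "GenotypeMatrix":
        idx = np.asarray(list(index), dtype=int)
        samples = [self.samples[i] for i in idx]
        groups = {s: g for s, g in self.groups.items() if s in set(samples)}
        return GenotypeMatrix(samples, self.markers, self.dosage[idx, :], groups)

    def with_markers(self, markers: Sequence[MarkerRecord]) -> "GenotypeMatrix":
        """Same dosages, updated marker metadata (e.g. flanks filled in)."""
        if len(markers) != self.n_markers:
            raise ValueError("marker count mismatch")
        return GenotypeMatrix(self.samples, markers, self.dosage, self.groups)


@dataclass
class PanelManifest:
    """Final panel description: one row per locus, sorted by (chrom, pos)."""

    table: pd.DataFrame  # columns: id, chrom, pos, ref, alt, source_set, pic

    COLUMNS = ("id", "chrom", "pos", "ref", "alt", "source_set", "pic")

    def __post_init__(self) -> None:
        missing = set(self.COLUMNS) - set(self.table.columns)
        if missing:
            raise ValueError(f"manifest missing columns: {sorted(missing)}")
        t = self.table.loc[:, list(self.COLUMNS)].copy()
        t["pos"] = t["pos"].astype(int)
        t = t.sort_values(["chrom", "pos"], kind="stable").reset_index(drop=True)
        if t.duplicated(["chrom", "pos"]).any():
            dups = t[t.duplicated(["chrom", "pos"], keep=False)]
            raise ValueError(
                "duplicate (chrom,pos) in manifest: "
                + ", ".join(f"{c}:{p}" for c, p in zip(dups.chrom, dups.pos))
            )
        self.table = t

    def __len__(self) -> int:
        return len(self.table)

    def to_bed(self) -> pd.DataFrame:
        """0-based half-open intervals: (pos-1, pos) for each SNV."""
        return pd.DataFrame(
            {
                "chrom": self.table.chrom,
                "start": self.table.pos - 1,
                "end": self.table.pos,
                "name": self.table.id,
            }
        )


__all__ = [
    "MISSING",
    "REGIONS",
    "MarkerRecord",
    "GenotypeMatrix",
    "PanelManifest",
    "replace",
    "field",
]
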