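"""Construction of co-binding regions from per-factor binding calls.

Binding calls are point events (a summit coordinate on a chromosome).
Calls from all factors of one cell type are pooled, expanded by a fixed
number of base pairs on each side of the summit, and transitively merged
into maximal non-overlapping regions.  Regions retaining at least
``min_sites`` calls become the documents of the topic-model corpus; the
corpus itself is summarised as a region x factor count matrix.

All coordinates are 0-based, half-open.
"""

from __future__ import annotations

import bisect
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

__all__ = [
    "BindingCall",
    "CoBindingRegion",
    "RegionTFMatrix",
    "read_binding_calls",
    "filter_blacklist",
    "build_cobinding_regions",
    "build_region_tf_matrix",
]


@dataclass(frozen=True)
class BindingCall:
    """A single TF binding event called at a summit position."""

    factor: str
    chrom: str
    summit: int
    motif_present: bool | None = None
    cell_type: str | None = None
    strength: float | None = None

    def __post_init__(self) -> None:
        if not self.factor:
            raise ValueError("factor label must be non-empty")
        if self.summit < 0:
            raise ValueError(f"summit must be >= 0, got {self.summit}")


@dataclass
class CoBindingRegion:
    """A merged interval holding the binding calls whose expanded spans chain-overlap."""

    chrom: str
    start: int
    end: int
    sites: list[BindingCall] = field(default_factory=list)
    cell_type: str | None = None

    @property
    def n_sites(self) -> int:
        return len(self.sites)

    def __post_init__(self) -> None:
        if self.end <= self.start:
            raise ValueError(f"end ({self.end}) must be > start ({self.start})")


@dataclass
class RegionTFMatrix:
    """Region x factor site-count matrix (the bag-of-words corpus)."""

    counts: np.ndarray  # (n_regions, n_factors) non-negative ints
    region_ids: list[str]
    factors: list[str]

    def __post_init__(self) -> None:
        self.counts = np.asarray(self.counts, dtype=np.int64)
        if self.counts.ndim != 2:
            raise ValueError("counts must be 2-dimensional")
        if self.counts.shape != (len(self.region_ids), len(self.factors)):
            raise ValueError("counts shape does not match region/factor labels")
        if (self.counts < 0).any():
            raise ValueError("counts must be non-negative")

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.counts, index=self.region_ids, columns=self.factors)

    @property
    def shape(self) -> tuple[int, int]:
        return self.counts.shape


def read_binding_calls(
    path: str | Path,
    factor: str,
    cell_type: str | None = None,
) -> list[BindingCall]:
    """Read point binding calls from a TSV file.

    Expected columns: chrom, summit[, motif_flag 0/1[, strength]].  Lines
    starting with ``#`` (and an optional ``chrom\\tsummit`` header line)
    are skipped.  Malformed coordinates raise with the offending line
    number.
    """
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(f"binding-call file not found: {path}")
    calls: list[BindingCall] = []
    seen_data = False
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line or line.startswith("#"):
                continue
            parts = line.split("\t")
            if not seen_data and parts[0].lower() in ("chrom", "chr", "chromosome"):
                continue
            seen_data = True
            if len(parts) < 2:
                raise ValueError(
                    f"{path}:{lineno}: expected at least 2 tab-separated columns"
                )
            try:
                summit = int(parts[1])
            except ValueError:
                raise ValueError(
                    f"{path}:{lineno}: non-integer summit coordinate {parts[1]!r}"
                ) from None
            motif: bool | None = None
            if len(parts) >= 3 and parts[2] != "":
                if parts[2] not in ("0", "1"):
                    raise ValueError(
                        f"{path}:{lineno}: motif flag must be 0 or 1, got {parts[2]!r}"
                    )
                motif = parts[2] == "1"
            strength: float | None = None
            if len(parts) >= 4 and parts[3] != "":
                strength = float(parts[3])
            calls.append(
                BindingCall(
                    factor=factor,
                    chrom=parts[0],
                    summit=summit,
                    motif_present=motif,
                    cell_type=cell_type,
                    strength=strength,
                )
            )
    if not calls:
        raise ValueError(f"no records in binding-call file: {path}")
    return calls


def _merge_intervals(intervals: Iterable[tuple[int, int]]) -> list[tuple[int, int]]:
    merged: list[tuple[int, int]] = []
    for start, end in sorted(intervals):
        if merged and start < merged[-1][1]:
            merged[-1] = (merged[-1][0], max(merged[-1][1], end))
        else:
            merged.append((start, end))
    return merged


def filter_blacklist(
    calls: Sequence[BindingCall],
    blacklist: Sequence[tuple[str, int, int]],
) -> list[BindingCall]:
    """Drop calls whose summit lies inside a blacklist interval (half-open)."""
    if not blacklist:
        return list(calls)
    by_chrom: dict[str, list[tuple[int, int]]] = {}
    for chrom, start, end in blacklist:
        by_chrom.setdefault(chrom, []).append((start, end))
    merged = {c: _merge_intervals(iv) for c, iv in by_chrom.items()}
    starts = {c: [s for s, _ in iv] for c, iv in merged.items()}

    kept: list[BindingCall] = []
    for call in calls:
        iv = merged.get(call.chrom)
        if iv is None:
            kept.append(call)
            continue
        i = bisect.bisect_right(starts[call.chrom], call.summit) - 1
        if i >= 0 and call.summit < iv[i][1]:
            continue  # summit in [start, end)
        kept.append(call)
    return kept


def build_cobinding_regions(
    calls: Sequence[BindingCall],
    expand_bp: int = 50,
    min_sites: int = 3,
) -> list[CoBindingRegion]:
    """Merge expanded binding calls into non-overlapping co-binding regions.

    Each summit is expanded to ``[summit - expand_bp, summit + expand_bp)``
    (clipped at 0); strictly overlapping intervals are merged transitively
    per chromosome.  Regions with fewer than ``min_sites`` calls are
    discarded.
    """
    if expand_bp < 0:
        raise ValueError("expand_bp must be >= 0")
    if min_sites < 1:
        raise ValueError("min_sites must be >= 1")

    by_chrom: dict[str, list[BindingCall]] = {}
    for call in calls:
        by_chrom.setdefault(call.chrom, []).append(call)

    regions: list[CoBindingRegion] = []
    for chrom in sorted(by_chrom):
        chrom_calls = sorted(by_chrom[chrom], key=lambda c: c.summit)
        cur_sites: list[BindingCall] = []
        cur_start = cur_end = 0
        for call in chrom_calls:
            start = max(0, call.summit - expand_bp)
            end = call.summit + expand_bp
            if end <= start:  # expand_bp == 0: keep a 1-bp point interval
                end = start + 1
            if cur_sites and start < cur_end:
                cur_end = max(cur_end, end)
                cur_sites.append(call)
            else:
                if cur_sites:
                    regions.append(
                        CoBindingRegion(chrom, cur_start, cur_end, cur_sites)
                    )
                cur_sites = [call]
                cur_start, cur_end = start, end
        if cur_sites:
            regions.append(CoBindingRegion(chrom, cur_start, cur_end, cur_sites))

    for region in regions:
        cts = {s.cell_type for s in region.sites}
        if len(cts) == 1:
            region.cell_type = next(iter(cts))
    return [r for r in regions if r.n_sites >= min_sites]


def build_region_tf_matrix(
    regions: Sequence[CoBindingRegion],
    factor_labels: Sequence[str],
) -> RegionTFMatrix:
    """Count each factor's sites per region over a fixed factor vocabulary."""
    factors = list(factor_labels)
    index = {f: i for i, f in enumerate(factors)}
    counts = np.zeros((len(regions), len(factors)), dtype=np.int64)
    region_ids = []
    for i, region in enumerate(regions):
        region_ids.append(f"{region.chrom}:{region.start}-{region.end}")
        for site in region.sites:
            j = index.get(site.factor)
            if j is None:
                raise KeyError(f"factor {site.factor!r} not in factor_labels")
            counts[i, j] += 1
    return RegionTFMatrix(counts=counts, region_ids=region_ids, factors=factors)
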