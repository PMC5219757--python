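"""External-evidence checks on discovered modules.

Covers rediscovery of physical protein-protein interaction pairs among
per-module main drivers (with a Monte-Carlo permutation test), fractions
of module-using regions overlapping annotation intervals, corpus
construction across cell types, per-module cell-type usage fractions,
and pairwise site-spacing histograms.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np
import pandas as pd

from .regions import BindingCall, CoBindingRegion, build_cobinding_regions, build_region_tf_matrix
from .topic_model import Corpus, corpus_from_matrix

__all__ = [
    "PPISet",
    "AnnotationTrack",
    "ppi_rediscovery",
    "ppi_permutation_test",
    "annotation_overlap_fractions",
    "cross_celltype_corpus",
    "celltype_fractions",
    "motif_spacing",
]


@dataclass
class PPISet:
    """Physical interaction pairs (bait, partner); duplicates collapsed,
    order within a pair is not meaningful for rediscovery."""

    pairs: list[tuple[str, str]]

    def __post_init__(self) -> None:
        seen = set()
        uniq = []
        for bait, partner in self.pairs:
            key = (bait, partner)
            if key not in seen:
                seen.add(key)
                uniq.append(key)
        self.pairs = uniq

    def __len__(self) -> int:
        return len(self.pairs)


@dataclass
class AnnotationTrack:
    label: str
    intervals: list[tuple[str, int, int]]  # 0-based half-open

    def by_chrom(self) -> dict[str, np.ndarray]:
        out: dict[str, list[tuple[int, int]]] = {}
        for chrom, s, e in self.intervals:
            out.setdefault(chrom, []).append((s, e))
        return {c: np.asarray(sorted(iv)) for c, iv in out.items()}


def ppi_rediscovery(
    drivers: list[list[str]], ppi: PPISet
) -> tuple[int, list[tuple[str, str]]]:
    """Count PPI pairs whose two factors are both main drivers of a same module."""
    driver_sets = [set(d) for d in drivers]
    recovered = []
    for a, b in ppi.pairs:
        if any(a in ds and b in ds for ds in driver_sets):
            recovered.append((a, b))
    return len(recovered), recovered


def ppi_permutation_test(
    drivers: list[list[str]],
    ppi: PPISet,
    vocabulary: Sequence[str],
    n_perm: int = 200,
    seed: int = 0,
) -> tuple[float, int, np.ndarray]:
    """Monte-Carlo p-value for the observed rediscovery count.

    Baits stay fixed; partners are redrawn uniformly from the factor
    vocabulary (self-pairs disallowed, duplicate pairs collapsed).
    Returns (p, observed count, permuted counts); p uses the +1-corrected
    estimator so it is never 0.
    """
    if n_perm < 1:
        raise ValueError("n_perm must be >= 1")
    rng = np.random.default_rng(seed)
    vocab = list(vocabulary)
    observed, _ = ppi_rediscovery(drivers, ppi)
    null = np.empty(n_perm, dtype=np.int64)
    for i in range(n_perm):
        pairs = []
        for bait, _partner in ppi.pairs:
            partner = vocab[rng.integers(len(vocab))]
            while partner == bait:
                partner = vocab[rng.integers(len(vocab))]
            pairs.append((bait, partner))
        null[i], _ = ppi_rediscovery(drivers, PPISet(pairs))
    p = (1 + int((null >= observed).sum())) / (1 + n_perm)
    return p, observed, null


def _region_overlaps_track(
    chrom: str, start: int, end: int, track_by_chrom: dict[str, np.ndarray]
) -> bool:
    iv = track_by_chrom.get(chrom)
    if iv is None:
        return False
    # half-open overlap of [start, end) with any [s, e): s < end and e > start
    i = np.searchsorted(iv[:, 0], end, side="left")
    return bool((iv[:i, 1] > start).any())


def annotation_overlap_fractions(
    usage: pd.DataFrame,
    region_coords: dict[str, tuple[str, int, int]],
    tracks: list[AnnotationTrack],
) -> pd.DataFrame:
    """For each module, the fraction of its using-regions overlapping each
    track by at least 1 bp.  Modules used by no region get NaN."""
    track_index = {t.label: t.by_chrom() for t in tracks}
    out = np.full((usage.shape[1], len(tracks)), np.nan)
    usage_arr = usage.to_numpy(dtype=bool)
    region_ids = list(usage.index)
    overlap_cache = np.zeros((len(region_ids), len(tracks)), dtype=bool)
    for i, rid in enumerate(region_ids):
        chrom, start, end = region_coords[rid]
        for j, t in enumerate(tracks):
            overlap_cache[i, j] = _region_overlaps_track(
                chrom, start, end, track_index[t.label]
            )
    for k in range(usage.shape[1]):
        users = usage_arr[:, k]
        if users.any():
            out[k] = overlap_cache[users].mean(axis=0)
    return pd.DataFrame(out, index=usage.columns, columns=[t.label for t in tracks])


def cross_celltype_corpus(
    calls_by_type: dict[str, list[BindingCall]],
    expand_bp: int = 50,
    min_sites: int = 3,
) -> tuple[Corpus, list[CoBindingRegion]]:
    """Build co-binding regions per cell type, then concatenate into one
    corpus with per-document origin labels.  Regions are never merged
    across cell types."""
    vocab = sorted({c.factor for calls in calls_by_type.values() for c in calls})
    all_docs: list[np.ndarray] = []
    all_ids: list[str] = []
    origins: list[str] = []
    all_regions: list[CoBindingRegion] = []
    for cell_type in sorted(calls_by_type):
        regions = build_cobinding_regions(
            calls_by_type[cell_type], expand_bp=expand_bp, min_sites=min_sites
        )
        for r in regions:
            r.cell_type = cell_type
        m = build_region_tf_matrix(regions, vocab)
        sub = corpus_from_matrix(m)
        all_docs.extend(sub.documents)
        all_ids.extend(f"{cell_type}|{rid}" for rid in sub.doc_ids)
        origins.extend([cell_type] * len(sub.documents))
        all_regions.extend(regions)
    return (
        Corpus(documents=all_docs, vocabulary=vocab, doc_ids=all_ids, origins=origins),
        all_regions,
    )


def celltype_fractions(usage: pd.DataFrame, origins: dict[str, str]) -> pd.DataFrame:
    """Per-module fraction of using-regions from each cell type (rows sum
    to 1; modules with no users get NaN)."""
    types = sorted(set(origins.values()))
    origin_arr = np.asarray([origins[r] for r in usage.index], dtype=object)
    usage_arr = usage.to_numpy(dtype=bool)
    out = np.full((usage.shape[1], len(types)), np.nan)
    for k in range(usage.shape[1]):
        users = usage_arr[:, k]
        n = users.sum()
        if n:
            out[k] = [(origin_arr[users] == t).sum() / n for t in types]
    return pd.DataFrame(out, index=usage.columns, columns=types)


def motif_spacing(
    anchor_calls: list[BindingCall],
    partner_calls: list[BindingCall],
    window: int = 100,
) -> dict[int, int]:
    """Signed distance (partner - anchor) to the nearest partner site
    within ``window`` bp, per anchor site; anchors with no partner in
    range are excluded.  Returns a distance histogram."""
    partners: dict[str, np.ndarray] = {}
    for chrom in {c.chrom for c in partner_calls}:
        partners[chrom] = np.asarray(
            sorted(c.summit for c in partner_calls if c.chrom == chrom)
        )
    hist: dict[int, int] = {}
    for call in anchor_calls:
        pos = partners.get(call.chrom)
        if pos is None or pos.size == 0:
            continue
        i = np.searchsorted(pos, call.summit)
        best = None
        for j in (i - 1, i):
            if 0 <= j < pos.size:
                d = int(pos[j] - call.summit)
                if abs(d) <= window and (best is None or abs(d) < abs(best)):
                    best = d
        if best is not None:
            hist[best] = hist.get(best, 0) + 1
    return dict(sorted(hist.items()))
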