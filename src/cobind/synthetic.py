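"""Synthetic binding-call datasets with planted module structure.

Every region draws one or two planted modules, then sites draw a module
and a factor from that module's distribution.  Region anchors are spaced
widely enough that the region-construction step provably recovers the
planted regions, so ground truth aligns 1:1 with built regions in
coordinate order.

Split factors (direct/indirect experiments) each get a pair of planted
modules: a "direct" module whose partner factors come from one pool and
an "indirect" module whose partners interpolate, by a divergence level
in [0, 1], between the same pool and a disjoint one.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy.optimize import linear_sum_assignment

from .evaluation import AnnotationTrack
from .regions import BindingCall
from .topic_model import ModuleTFMatrix

__all__ = [
    "SyntheticConfig",
    "GroundTruth",
    "SyntheticDataset",
    "RecoveryMetrics",
    "generate",
    "score_recovery",
]


@dataclass
class SyntheticConfig:
    n_factors: int = 30
    n_modules: int = 6  # base modules (split factors add 2 each)
    phi_concentration: float = 0.05
    top_factors: int = 8  # planted distributions truncated to this support
    n_regions: int = 3000
    multi_module_fraction: float = 0.2
    single_sites_lambda: float = 5.0  # single-module regions: 3 + Poisson
    site_count_dispersion: float | None = None  # Gamma shape; None = pure Poisson
    module_probs: list[float] | None = None  # base-module usage; None = uniform
    pair_sites_lambda: float = 1.5  # two-module regions: per module 8 + Poisson
    chrom: str = "chr1"
    anchor_spacing: int = 1000
    anchor_jitter: int = 100
    site_jitter: int = 40
    expand_bp: int = 50  # used only for the never-merge feasibility check
    split_factors: dict[str, float] = field(default_factory=dict)  # label -> divergence
    partner_pool_size: int = 4
    split_factor_weight: float = 0.4
    cell_types: tuple[str, ...] = ()
    celltype_bias: dict[str, list[float]] = field(default_factory=dict)
    emit_annotations: bool = False
    annot_p_on: float = 0.9
    annot_p_off: float = 0.05
    seed: int = 0

    def validate(self) -> None:
        if self.n_modules < 1 or self.n_factors < 2:
            raise ValueError("need at least 1 module and 2 factors")
        if not 0 <= self.multi_module_fraction <= 1:
            raise ValueError("multi_module_fraction must be in [0, 1]")
        min_gap = self.anchor_spacing - 2 * self.anchor_jitter
        if min_gap <= 2 * (self.expand_bp + self.site_jitter):
            raise ValueError(
                "anchor spacing too small: planted regions could merge "
                f"(min anchor gap {min_gap} <= 2*(expand_bp + site_jitter))"
            )
        n_split = len(self.split_factors)
        needed = 2 * self.partner_pool_size
        if n_split and self.n_factors - n_split < needed:
            raise ValueError(
                f"not enough non-split factors for partner pools (need {needed})"
            )
        if self.top_factors > self.n_factors:
            raise ValueError("top_factors exceeds n_factors")
        for f, div in self.split_factors.items():
            if not 0 <= div <= 1:
                raise ValueError(f"divergence for {f} must be in [0, 1]")
        for ct, bias in self.celltype_bias.items():
            if ct not in self.cell_types:
                raise ValueError(f"bias given for unknown cell type {ct!r}")


@dataclass
class GroundTruth:
    phi: np.ndarray  # (K_total, V) planted module-factor distributions
    vocabulary: list[str]  # split vocabulary, sorted (matches pipeline corpora)
    module_names: list[str]
    region_modules: list[tuple[int, ...]]
    region_module_counts: list[dict[int, int]]
    token_words: list[np.ndarray]  # per region, vocab index per token (sorted)
    token_labels: list[np.ndarray]  # per region, planted module per token
    region_anchor: np.ndarray
    region_cell_type: list[str | None]
    region_span: list[tuple[str, int, int]]  # expanded span of the emitted sites

    @property
    def n_regions(self) -> int:
        return len(self.region_modules)

    @property
    def n_sites(self) -> int:
        return sum(len(t) for t in self.token_words)


@dataclass
class SyntheticDataset:
    calls: list[BindingCall]
    annotations: list[AnnotationTrack]
    truth: GroundTruth
    config: SyntheticConfig

    def calls_by_type(self) -> dict[str, list[BindingCall]]:
        out: dict[str, list[BindingCall]] = {}
        for c in self.calls:
            out.setdefault(c.cell_type or "all", []).append(c)
        return out


def _build_vocabulary(cfg: SyntheticConfig) -> tuple[list[str], list[str], dict[str, str]]:
    """Base factor labels, split vocabulary (sorted), and base->variant info."""
    base = [f"TF{i:02d}" for i in range(1, cfg.n_factors + 1)]
    unknown = set(cfg.split_factors) - set(base)
    if unknown:
        raise ValueError(f"split factors not in the factor set: {sorted(unknown)}")
    vocab = []
    for f in base:
        if f in cfg.split_factors:
            vocab.extend([f"d{f}", f"i{f}"])
        else:
            vocab.append(f)
    return base, sorted(vocab), {}


def _planted_phi(cfg: SyntheticConfig, vocab: list[str], rng: np.random.Generator):
    """Planted distributions: sparse Dirichlet base modules over non-split
    factors, plus a direct and an indirect module per split factor."""
    vidx = {w: i for i, w in enumerate(vocab)}
    V = len(vocab)
    nonsplit = [w for w in vocab if not (w[1:] in cfg.split_factors and w[0] in "di")]

    # Partner pools are carved out first and are globally disjoint: if a
    # factor's direct/indirect contexts shared partners with other pools
    # or with base modules, the planted topics would couple and stop
    # being separately recoverable.
    pool_order = rng.permutation(len(nonsplit))
    pool_cursor = 0
    pools: dict[str, tuple[list[str], list[str]]] = {}
    for f in sorted(cfg.split_factors):
        take = 2 * cfg.partner_pool_size
        idx = [int(pool_order[(pool_cursor + j) % len(nonsplit)]) for j in range(take)]
        pool_cursor += take
        pools[f] = (
            [nonsplit[i] for i in idx[: cfg.partner_pool_size]],
            [nonsplit[i] for i in idx[cfg.partner_pool_size :]],
        )
    pooled = {w for a, b in pools.values() for w in a + b}
    base_support = [w for w in nonsplit if w not in pooled] or nonsplit

    phi_rows: list[np.ndarray] = []
    names: list[str] = []
    n_base_support = min(len(base_support), max(2, cfg.top_factors))
    for k in range(cfg.n_modules):
        weights = rng.dirichlet(np.full(len(base_support), cfg.phi_concentration))
        top = np.argsort(-weights)[:n_base_support]
        row = np.zeros(V)
        for j in top:
            row[vidx[base_support[j]]] = weights[j]
        phi_rows.append(row / row.sum())
        names.append(f"base_{k}")

    for f in sorted(cfg.split_factors):
        div = cfg.split_factors[f]
        pool_a, pool_b = pools[f]
        w_x = cfg.split_factor_weight
        share = (1.0 - w_x) / cfg.partner_pool_size

        row_d = np.zeros(V)
        row_d[vidx[f"d{f}"]] = w_x
        for w in pool_a:
            row_d[vidx[w]] += share
        phi_rows.append(row_d)
        names.append(f"direct_{f}")

        row_i = np.zeros(V)
        row_i[vidx[f"i{f}"]] = w_x
        for w in pool_a:
            row_i[vidx[w]] += share * (1.0 - div)
        for w in pool_b:
            row_i[vidx[w]] += share * div
        phi_rows.append(row_i)
        names.append(f"indirect_{f}")

    return np.vstack(phi_rows), names


def _module_probs(cfg: SyntheticConfig, n_total: int) -> np.ndarray:
    """Base modules share 20% of the mass when split-factor modules exist,
    otherwise everything; split-factor modules share the rest equally."""
    n_split_modules = 2 * len(cfg.split_factors)
    p = np.zeros(n_total)
    if n_split_modules:
        p[: cfg.n_modules] = 0.2 / cfg.n_modules
        p[cfg.n_modules :] = 0.8 / n_split_modules
    elif cfg.module_probs is not None:
        q = np.asarray(cfg.module_probs, dtype=float)
        if q.shape != (n_total,) or (q < 0).any() or q.sum() <= 0:
            raise ValueError("module_probs must be non-negative with one entry per module")
        p = q / q.sum()
    else:
        p[:] = 1.0 / n_total
    return p


def generate(config: SyntheticConfig) -> SyntheticDataset:
    """Generate binding calls, optional annotation tracks, and ground truth."""
    cfg = config
    cfg.validate()
    rng = np.random.default_rng(cfg.seed)
    base_factors, vocab, _ = _build_vocabulary(cfg)
    vidx = {w: i for i, w in enumerate(vocab)}
    phi, module_names = _planted_phi(cfg, vocab, rng)
    K_total = phi.shape[0]
    base_probs = _module_probs(cfg, K_total)

    cell_types = cfg.cell_types or (None,)
    bias = {
        ct: np.asarray(cfg.celltype_bias.get(ct, np.ones(K_total)), dtype=float)
        for ct in cell_types
        if ct is not None
    }

    calls: list[BindingCall] = []
    region_modules: list[tuple[int, ...]] = []
    region_counts: list[dict[int, int]] = []
    token_words: list[np.ndarray] = []
    token_labels: list[np.ndarray] = []
    anchors = np.empty(cfg.n_regions, dtype=np.int64)
    region_ct: list[str | None] = []
    region_span: list[tuple[str, int, int]] = []

    for r in range(cfg.n_regions):
        anchor = (r + 1) * cfg.anchor_spacing + int(
            rng.integers(-cfg.anchor_jitter, cfg.anchor_jitter + 1)
        )
        anchors[r] = anchor
        ct = cell_types[int(rng.integers(len(cell_types)))]
        probs = base_probs.copy()
        if ct is not None and ct in bias:
            probs = probs * bias[ct]
        probs = probs / probs.sum()

        if K_total >= 2 and rng.random() < cfg.multi_module_fraction:
            mods = tuple(
                sorted(rng.choice(K_total, size=2, replace=False, p=probs).tolist())
            )
            # near-balanced counts: the within-region z>1 usage rule only
            # fires for a minor module holding >~3/4 of the major's sites
            m = 8 + int(rng.poisson(cfg.pair_sites_lambda))
            counts = {mods[0]: m, mods[1]: m + int(rng.integers(0, 2))}
        else:
            mods = (int(rng.choice(K_total, p=probs)),)
            lam = cfg.single_sites_lambda
            if cfg.site_count_dispersion is not None:
                # gamma-mixed Poisson: heavy-tailed region sizes
                lam = rng.gamma(
                    cfg.site_count_dispersion, lam / cfg.site_count_dispersion
                )
            counts = {mods[0]: 3 + int(rng.poisson(lam))}

        words = []
        labels = []
        for k, n in counts.items():
            ws = rng.choice(len(vocab), size=n, p=phi[k])
            words.extend(int(w) for w in ws)
            labels.extend([k] * n)
        words = np.asarray(words, dtype=np.int64)
        labels = np.asarray(labels, dtype=np.int64)
        order = np.argsort(words, kind="stable")  # matches corpus token layout
        words, labels = words[order], labels[order]

        n = len(words)
        offsets = rng.integers(-cfg.site_jitter, cfg.site_jitter + 1, size=n)
        summits = anchor + offsets
        lo = int(summits.min()) - cfg.expand_bp
        hi = int(summits.max()) + cfg.expand_bp
        for w, s in zip(words, summits):
            label = vocab[w]
            if label[0] == "d" and label[1:] in cfg.split_factors:
                factor, motif = label[1:], True
            elif label[0] == "i" and label[1:] in cfg.split_factors:
                factor, motif = label[1:], False
            else:
                factor, motif = label, None
            calls.append(
                BindingCall(
                    factor=factor,
                    chrom=cfg.chrom,
                    summit=int(s),
                    motif_present=motif,
                    cell_type=ct,
                )
            )

        region_modules.append(mods)
        region_counts.append(counts)
        token_words.append(words)
        token_labels.append(labels)
        region_ct.append(ct)
        region_span.append((cfg.chrom, lo, hi))

    annotations: list[AnnotationTrack] = []
    if cfg.emit_annotations:
        for k in range(K_total):
            intervals = []
            for r in range(cfg.n_regions):
                p = cfg.annot_p_on if k in region_modules[r] else cfg.annot_p_off
                if rng.random() < p:
                    intervals.append(region_span[r])
            annotations.append(AnnotationTrack(label=f"track_{module_names[k]}", intervals=intervals))

    truth = GroundTruth(
        phi=phi,
        vocabulary=vocab,
        module_names=module_names,
        region_modules=region_modules,
        region_module_counts=region_counts,
        token_words=token_words,
        token_labels=token_labels,
        region_anchor=anchors,
        region_cell_type=region_ct,
        region_span=region_span,
    )
    return SyntheticDataset(calls=calls, annotations=annotations, truth=truth, config=cfg)


@dataclass
class RecoveryMetrics:
    mean_cosine: float
    k_inferred: int
    k_true: int
    token_accuracy: float
    matching: dict[int, int]  # inferred module -> planted module


def _cosine_matrix(a: np.ndarray, b: np.ndarray) -> np.ndarray:
    an = a / np.maximum(np.linalg.norm(a, axis=1, keepdims=True), 1e-300)
    bn = b / np.maximum(np.linalg.norm(b, axis=1, keepdims=True), 1e-300)
    return an @ bn.T


def score_recovery(truth: GroundTruth, mtm: ModuleTFMatrix, assignments) -> RecoveryMetrics:
    """Score inferred modules against the planted ones.

    Inferred module rows (normalized) are Hungarian-matched to planted
    distributions by cosine similarity.  Token accuracy maps each
    inferred module to its matched planted module; tokens in unmatched
    inferred modules count as wrong.  The assignment table must come from
    a corpus whose documents are the planted regions in coordinate order.
    """
    if list(mtm.factors) != list(truth.vocabulary):
        raise ValueError("module-TF matrix vocabulary does not match ground truth")
    inferred = mtm.counts.astype(float)
    cos = _cosine_matrix(inferred, truth.phi)
    rows, cols = linear_sum_assignment(-cos)
    matching = {int(r): int(c) for r, c in zip(rows, cols)}
    mean_cos = float(cos[rows, cols].mean())

    inferred_z = assignments["module"].to_numpy()
    n_per_region = np.asarray([len(t) for t in truth.token_words])
    if inferred_z.size != n_per_region.sum():
        raise ValueError("assignment table size does not match ground truth")
    true_labels = np.concatenate(truth.token_labels)
    mapped = np.asarray(
        [matching.get(int(m), -1) for m in inferred_z], dtype=np.int64
    )
    accuracy = float((mapped == true_labels).mean())

    return RecoveryMetrics(
        mean_cosine=mean_cos,
        k_inferred=mtm.n_modules,
        k_true=truth.phi.shape[0],
        token_accuracy=accuracy,
        matching=matching,
    )
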