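"""Direct (motif-present) versus indirect (motif-absent) binding analysis.

Sequence-specific factors are split into pseudo-factors dX and iX before
region construction and model fitting.  The divergence between a
factor's direct and indirect co-binding contexts is summarized by a
diversification score (Pearson correlation distance between the dX and
iX module-participation vectors), and by how well a random forest can
predict direct/indirect status from the other factors' binding alone.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.stats import pearsonr
from sklearn.ensemble import RandomForestClassifier
from sklearn.model_selection import train_test_split

from .regions import BindingCall, RegionTFMatrix
from .topic_model import ModuleTFMatrix

__all__ = [
    "FactorSplitSpec",
    "DiversificationScore",
    "RFReport",
    "split_factors",
    "direct_indirect_correlation",
    "diversification_scores",
    "predict_direct_indirect",
    "diversification_vs_accuracy",
]


@dataclass
class FactorSplitSpec:
    """Which factors are sequence-specific and how their variants are labeled."""

    sequence_specific: frozenset[str]

    def __init__(self, sequence_specific) -> None:
        self.sequence_specific = frozenset(sequence_specific)

    def direct_label(self, factor: str) -> str:
        return f"d{factor}"

    def indirect_label(self, factor: str) -> str:
        return f"i{factor}"

    def split_vocabulary(self, factors: list[str]) -> list[str]:
        out = []
        for f in factors:
            if f in self.sequence_specific:
                out.extend([self.direct_label(f), self.indirect_label(f)])
            else:
                out.append(f)
        return out


@dataclass
class DiversificationScore:
    factor: str
    score: float  # 1 - Pearson(dX vector, iX vector), in [0, 2]


@dataclass
class RFReport:
    factor: str
    accuracies: list[float]  # one per fit
    mean_accuracy: float
    balanced_accuracies: list[float]
    mean_balanced_accuracy: float
    n_direct: int
    n_indirect: int
    n_mixed_excluded: int = 0


def split_factors(calls: list[BindingCall], spec: FactorSplitSpec) -> list[BindingCall]:
    """Relabel each sequence-specific factor's calls as dX/iX by motif flag."""
    out: list[BindingCall] = []
    for call in calls:
        if call.factor in spec.sequence_specific:
            if call.motif_present is None:
                raise ValueError(
                    f"call for sequence-specific factor {call.factor!r} at "
                    f"{call.chrom}:{call.summit} is missing its motif flag"
                )
            label = (
                spec.direct_label(call.factor)
                if call.motif_present
                else spec.indirect_label(call.factor)
            )
            out.append(
                BindingCall(
                    factor=label,
                    chrom=call.chrom,
                    summit=call.summit,
                    motif_present=call.motif_present,
                    cell_type=call.cell_type,
                    strength=call.strength,
                )
            )
        else:
            out.append(call)
    return out


def _column(mtm: ModuleTFMatrix, label: str) -> np.ndarray:
    try:
        j = mtm.factors.index(label)
    except ValueError:
        raise KeyError(f"factor {label!r} not in module-TF matrix") from None
    return np.asarray(mtm.counts[:, j], dtype=float)


def _safe_pearson(a: np.ndarray, b: np.ndarray) -> float:
    if a.std() == 0 or b.std() == 0:
        return 0.0
    return float(np.corrcoef(a, b)[0, 1])


def direct_indirect_correlation(mtm: ModuleTFMatrix, spec: FactorSplitSpec) -> pd.DataFrame:
    """Pearson correlation between each dX column and each iY column."""
    split = sorted(
        f
        for f in spec.sequence_specific
        if spec.direct_label(f) in mtm.factors and spec.indirect_label(f) in mtm.factors
    )
    if not split:
        raise ValueError("no split factors present in the module-TF matrix")
    out = np.zeros((len(split), len(split)))
    for i, fx in enumerate(split):
        dx = _column(mtm, spec.direct_label(fx))
        for j, fy in enumerate(split):
            iy = _column(mtm, spec.indirect_label(fy))
            out[i, j] = _safe_pearson(dx, iy)
    return pd.DataFrame(
        out,
        index=[spec.direct_label(f) for f in split],
        columns=[spec.indirect_label(f) for f in split],
    )


def diversification_scores(mtm: ModuleTFMatrix, spec: FactorSplitSpec) -> list[DiversificationScore]:
    """1 - Pearson(dX module vector, iX module vector) per split factor."""
    scores = []
    for f in sorted(spec.sequence_specific):
        d_label, i_label = spec.direct_label(f), spec.indirect_label(f)
        if d_label not in mtm.factors or i_label not in mtm.factors:
            continue
        r = _safe_pearson(_column(mtm, d_label), _column(mtm, i_label))
        scores.append(DiversificationScore(factor=f, score=1.0 - r))
    return scores


def predict_direct_indirect(
    matrix: RegionTFMatrix,
    factor: str,
    spec: FactorSplitSpec,
    seeds: tuple[int, ...] = (1, 2, 3, 4, 5),
    n_estimators: int = 500,
    test_size: float = 0.2,
) -> RFReport:
    """Random-forest prediction of a factor's direct/indirect status from
    the co-binding of all other factors.

    Regions containing dX xor iX sites become samples (mixed regions are
    excluded and counted); features are the other factors' site counts
    with every other split factor's d/i columns summed and X's own
    columns removed.  One fit per seed on a seeded 80/20 split.
    """
    if factor not in spec.sequence_specific:
        raise ValueError(f"factor {factor!r} is not in the split set")
    d_label, i_label = spec.direct_label(factor), spec.indirect_label(factor)
    frame = matrix.to_frame()
    for lbl in (d_label, i_label):
        if lbl not in frame.columns:
            raise ValueError(f"column {lbl!r} missing from the region-TF matrix")

    has_d = frame[d_label].to_numpy() > 0
    has_i = frame[i_label].to_numpy() > 0
    mixed = has_d & has_i
    keep = (has_d | has_i) & ~mixed
    y = has_d[keep].astype(int)

    feat = frame.loc[keep].drop(columns=[d_label, i_label])
    for other in spec.sequence_specific:
        if other == factor:
            continue
        do, io = spec.direct_label(other), spec.indirect_label(other)
        if do in feat.columns and io in feat.columns:
            feat[other] = feat[do] + feat[io]
            feat = feat.drop(columns=[do, io])
    X = feat.to_numpy(dtype=float)

    n_direct, n_indirect = int(y.sum()), int((1 - y).sum())
    if min(n_direct, n_indirect) < 5:
        raise ValueError(
            f"insufficient data for {factor!r}: {n_direct} direct / "
            f"{n_indirect} indirect regions"
        )

    accs, baccs = [], []
    for seed in seeds:
        Xtr, Xte, ytr, yte = train_test_split(
            X, y, test_size=test_size, random_state=seed, stratify=y
        )
        rf = RandomForestClassifier(
            n_estimators=n_estimators, max_features="sqrt", random_state=seed
        )
        rf.fit(Xtr, ytr)
        pred = rf.predict(Xte)
        accs.append(float((pred == yte).mean()))
        sens = float((pred[yte == 1] == 1).mean()) if (yte == 1).any() else 0.0
        spec_ = float((pred[yte == 0] == 0).mean()) if (yte == 0).any() else 0.0
        baccs.append(0.5 * (sens + spec_))

    return RFReport(
        factor=factor,
        accuracies=accs,
        mean_accuracy=float(np.mean(accs)),
        balanced_accuracies=baccs,
        mean_balanced_accuracy=float(np.mean(baccs)),
        n_direct=n_direct,
        n_indirect=n_indirect,
        n_mixed_excluded=int(mixed.sum()),
    )


def diversification_vs_accuracy(
    scores: list[DiversificationScore], reports: list[RFReport]
) -> float:
    """Pearson r between diversification score and mean RF accuracy."""
    by_factor = {r.factor: r.mean_accuracy for r in reports}
    pairs = [(s.score, by_factor[s.factor]) for s in scores if s.factor in by_factor]
    if len(pairs) < 2:
        raise ValueError("need at least 2 factors with both score and report")
    x, y = zip(*pairs)
    r, _ = pearsonr(x, y)
    return float(r)
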