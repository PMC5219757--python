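"""HDP topic model over co-binding regions.

Regions are documents, TF binding sites are words, and the inferred
topics are the regulatory modules.  Inference is a direct-assignment
collapsed Gibbs sampler with stick weights resampled each sweep and the
concentration parameters resampled under vague Gamma(1, 1) priors.  The
number of modules is inferred from the data.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from . import _hdp_kernels as _k
from .regions import RegionTFMatrix

logger = logging.getLogger(__name__)

__all__ = [
    "Corpus",
    "HDPState",
    "ModuleTFMatrix",
    "corpus_from_matrix",
    "fit_hdp",
    "fit_hdp_multistart",
    "extract_outputs",
]


@dataclass
class Corpus:
    """Bag-of-words corpus: one token list per region, integer factor ids."""

    documents: list[np.ndarray]
    vocabulary: list[str]
    doc_ids: list[str]
    origins: list[str] | None = None  # e.g. cell type of each document

    def __post_init__(self) -> None:
        V = len(self.vocabulary)
        for doc in self.documents:
            if len(doc) and doc.max() >= V:
                raise ValueError("token index out of vocabulary range")

    @property
    def n_documents(self) -> int:
        return len(self.documents)

    @property
    def n_tokens(self) -> int:
        return sum(len(d) for d in self.documents)

    def to_counts(self) -> np.ndarray:
        V = len(self.vocabulary)
        counts = np.zeros((len(self.documents), V), dtype=np.int64)
        for i, doc in enumerate(self.documents):
            np.add.at(counts[i], doc, 1)
        return counts


@dataclass
class ModuleTFMatrix:
    """Module x factor site-count matrix: row k counts the sites each factor contributed to module k."""

    counts: np.ndarray  # (K, V) ints
    factors: list[str]
    module_ids: list[int] = field(default_factory=list)

    def __post_init__(self) -> None:
        self.counts = np.asarray(self.counts, dtype=np.int64)
        if not self.module_ids:
            self.module_ids = list(range(self.counts.shape[0]))

    @property
    def n_modules(self) -> int:
        return self.counts.shape[0]

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            self.counts,
            index=[f"module_{m}" for m in self.module_ids],
            columns=self.factors,
        )


@dataclass
class HDPState:
    """Final sampler state plus the per-iteration log-likelihood trace."""

    z: np.ndarray  # flat topic slot per token
    doc_offsets: np.ndarray  # token span of each document
    token_word: np.ndarray
    n_kw: np.ndarray  # slot x word counts (includes dead slots)
    n_k: np.ndarray
    beta: np.ndarray
    eta: float
    alpha0: float
    gamma: float
    seed: int
    loglik_trace: np.ndarray
    multistart_traces: dict[int, np.ndarray] = field(default_factory=dict)

    @property
    def active_slots(self) -> np.ndarray:
        return np.flatnonzero(self.n_k > 0)

    @property
    def n_topics(self) -> int:
        return int((self.n_k > 0).sum())

    @property
    def final_loglik(self) -> float:
        return float(self.loglik_trace[-1])


def corpus_from_matrix(m: RegionTFMatrix | pd.DataFrame) -> Corpus:
    """Expand a region x factor count matrix into token lists.

    Tokens within a document are laid out in factor-index order, which is
    deterministic.  All-zero rows are excluded (they cannot occur after
    the min-sites filter) with a warning.
    """
    if isinstance(m, pd.DataFrame):
        counts = m.to_numpy(dtype=np.int64)
        region_ids = [str(i) for i in m.index]
        factors = [str(c) for c in m.columns]
    else:
        counts, region_ids, factors = m.counts, m.region_ids, m.factors
    if (counts < 0).any():
        raise ValueError("counts must be non-negative")
    docs: list[np.ndarray] = []
    ids: list[str] = []
    n_dropped = 0
    for i in range(counts.shape[0]):
        row = counts[i]
        if row.sum() == 0:
            n_dropped += 1
            continue
        docs.append(np.repeat(np.arange(row.size, dtype=np.int32), row))
        ids.append(region_ids[i])
    if n_dropped:
        logger.warning("excluded %d all-zero regions from the corpus", n_dropped)
    return Corpus(documents=docs, vocabulary=list(factors), doc_ids=ids)


def _flatten(corpus: Corpus) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    doc_offsets = np.zeros(len(corpus.documents) + 1, dtype=np.int64)
    for i, doc in enumerate(corpus.documents):
        doc_offsets[i + 1] = doc_offsets[i] + len(doc)
    token_word = np.concatenate([np.asarray(d, dtype=np.int32) for d in corpus.documents])
    token_doc = np.repeat(
        np.arange(len(corpus.documents), dtype=np.int32), np.diff(doc_offsets)
    )
    return token_word, token_doc, doc_offsets


def _check_counts(z, token_word, token_doc, n_dk, n_kw, n_k) -> None:
    Kmax, V = n_kw.shape
    ref_kw = np.zeros((Kmax, V), dtype=np.int32)
    ref_dk = np.zeros_like(n_dk)
    np.add.at(ref_kw, (z, token_word), 1)
    np.add.at(ref_dk, (token_doc, z), 1)
    if not (
        np.array_equal(ref_kw, n_kw)
        and np.array_equal(ref_dk, n_dk)
        and np.array_equal(ref_kw.sum(axis=1), n_k)
    ):
        raise AssertionError("count tables inconsistent with assignments")


def fit_hdp(
    corpus: Corpus,
    eta: float = 0.1,
    max_iter: int = 2000,
    seed: int = 1,
    alpha0: float = 1.0,
    gamma: float = 1.0,
    resample_concentrations: bool = True,
    k_init: int = 1,
    init: str = "random",
    k_max: int = 64,
    debug: bool = False,
) -> HDPState:
    """Run the collapsed Gibbs sampler for ``max_iter`` full sweeps.

    The topic count is inferred; ``k_max`` only sizes the slot pool and
    grows automatically if the sampler needs more topics.  Runs are fully
    reproducible given ``seed``.

    ``init='random'`` scatters tokens over ``k_init`` topics;
    ``init='cluster'`` seeds topics from a k-means clustering of the
    document count vectors into ``k_init`` clusters.  Over-segmented
    cluster initialization helps because single-site Gibbs merges
    redundant topics far more readily than it splits conflated ones.
    """
    if max_iter < 1:
        raise ValueError("max_iter must be >= 1")
    if eta <= 0:
        raise ValueError("eta must be > 0")
    if corpus.n_documents == 0 or corpus.n_tokens == 0:
        raise ValueError("corpus is empty")

    token_word, token_doc, doc_offsets = _flatten(corpus)
    doc_len = np.diff(doc_offsets).astype(np.int64)
    V = len(corpus.vocabulary)
    D = corpus.n_documents
    Kmax = max(k_max, k_init + 1)

    z = np.zeros(token_word.shape[0], dtype=np.int32)
    n_dk = np.zeros((D, Kmax), dtype=np.int32)
    n_kw = np.zeros((Kmax, V), dtype=np.int32)
    n_k = np.zeros(Kmax, dtype=np.int64)
    k_init = min(k_init, max(1, corpus.n_tokens))
    if init == "cluster" and k_init > 1:
        from sklearn.cluster import KMeans

        counts = corpus.to_counts().astype(float)
        k_init = min(k_init, D)
        labels = KMeans(n_clusters=k_init, n_init=3, random_state=seed).fit_predict(counts)
        _k.init_state(token_word, token_doc, n_dk, n_kw, n_k, z, 1, seed)
        # overwrite the random init with the cluster assignment
        n_dk[:] = 0
        n_kw[:] = 0
        n_k[:] = 0
        z[:] = labels.astype(np.int32)[token_doc]
        np.add.at(n_dk, (token_doc, z), 1)
        np.add.at(n_kw, (z, token_word), 1)
        np.add.at(n_k, z, 1)
    elif init == "random":
        _k.init_state(token_word, token_doc, n_dk, n_kw, n_k, z, k_init, seed)
    else:
        raise ValueError("init must be 'random' or 'cluster'")

    beta = np.zeros(Kmax, dtype=np.float64)
    beta[:k_init] = 1.0 / (k_init + 1)
    beta_u = np.array([1.0 / (k_init + 1)])
    T_k = np.zeros(Kmax, dtype=np.int64)

    trace = np.empty(max_iter, dtype=np.float64)
    for it in range(max_iter):
        overflow = _k.sweep(
            token_word, token_doc, z, n_dk, n_kw, n_k, beta, beta_u, alpha0, gamma, eta
        )
        _k.sample_tables(n_dk, n_k, beta, alpha0, T_k)
        _k.sample_beta(n_k, T_k, beta, beta_u, gamma)
        T_total = int(T_k.sum())
        K_active = int((n_k > 0).sum())
        if resample_concentrations:
            alpha0 = float(_k.sample_alpha0(alpha0, doc_len, T_total, 1.0, 1.0))
            gamma = float(_k.sample_gamma(gamma, K_active, T_total, 1.0, 1.0))
        trace[it] = _k.log_likelihood(n_dk, n_kw, n_k, doc_len, beta, alpha0, eta)
        if not np.isfinite(trace[it]):
            raise FloatingPointError(f"non-finite log-likelihood at sweep {it}")
        if debug:
            _check_counts(z, token_word, token_doc, n_dk, n_kw, n_k)
        if overflow:
            grow = Kmax
            n_dk = np.hstack([n_dk, np.zeros((D, grow), dtype=np.int32)])
            n_kw = np.vstack([n_kw, np.zeros((grow, V), dtype=np.int32)])
            n_k = np.concatenate([n_k, np.zeros(grow, dtype=np.int64)])
            beta = np.concatenate([beta, np.zeros(grow)])
            T_k = np.concatenate([T_k, np.zeros(grow, dtype=np.int64)])
            Kmax += grow
            logger.info("slot pool grown to %d at sweep %d", Kmax, it)

    return HDPState(
        z=z,
        doc_offsets=doc_offsets,
        token_word=token_word,
        n_kw=n_kw,
        n_k=n_k,
        beta=beta,
        eta=eta,
        alpha0=alpha0,
        gamma=gamma,
        seed=seed,
        loglik_trace=trace,
    )


def fit_hdp_multistart(
    corpus: Corpus,
    seeds: tuple[int, ...] = (1, 2, 3),
    eta: float = 0.1,
    max_iter: int = 2000,
    **kwargs,
) -> HDPState:
    """Fit once per seed and keep the run with the highest final data likelihood."""
    if not seeds:
        raise ValueError("at least one seed is required")
    states = [fit_hdp(corpus, eta=eta, max_iter=max_iter, seed=s, **kwargs) for s in seeds]
    best = max(states, key=lambda st: st.final_loglik)
    best.multistart_traces = {st.seed: st.loglik_trace for st in states}
    for st in states:
        logger.info(
            "seed %d: final loglik %.2f, K=%d%s",
            st.seed,
            st.final_loglik,
            st.n_topics,
            " (selected)" if st is best else "",
        )
    return best


def extract_outputs(state: HDPState, corpus: Corpus) -> tuple[ModuleTFMatrix, pd.DataFrame]:
    """Densify the fitted state into the module-TF matrix and assignment table.

    Empty topic slots are dropped and modules relabeled 0..K-1 by
    descending total site count.  The assignment table has one record per
    token: (region_id, site_index, factor, module).
    """
    active = state.active_slots
    order = active[np.argsort(-state.n_k[active], kind="stable")]
    relabel = np.full(state.n_kw.shape[0], -1, dtype=np.int64)
    relabel[order] = np.arange(order.size)

    counts = state.n_kw[order].astype(np.int64)
    mtm = ModuleTFMatrix(counts=counts, factors=list(corpus.vocabulary))

    modules = relabel[state.z]
    region_col = np.repeat(
        np.arange(corpus.n_documents), np.diff(state.doc_offsets)
    )
    site_index = np.concatenate(
        [np.arange(n, dtype=np.int64) for n in np.diff(state.doc_offsets)]
    ) if corpus.n_documents else np.empty(0, dtype=np.int64)
    vocab = np.asarray(corpus.vocabulary, dtype=object)
    table = pd.DataFrame(
        {
            "region_id": np.asarray(corpus.doc_ids, dtype=object)[region_col],
            "site_index": site_index,
            "factor": vocab[state.token_word],
            "module": modules,
        }
    )
    if corpus.origins is not None:
        origins = np.asarray(corpus.origins, dtype=object)
        table["origin"] = origins[region_col]
    return mtm, table
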