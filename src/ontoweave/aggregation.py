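"""Vote aggregation: majority vote and the generative label model.

The label model treats each source j as conditionally independent given the
true label y: with probability c_j it votes (coverage, independent of y), and
a vote equals y with probability a_j (the source accuracy), otherwise it is
uniform over the k wrong classes.  Source accuracies are recoverable without
gold labels from the agreement rates between sources: for binary tasks the
closed-form triplet method inverts pairwise agreement products, and in
general an EM fit of the conditional-independence model maximizes the
marginal likelihood of the observed label matrix.  The fitted model yields a
posterior distribution over the true label of every word, i.e. denoised
consensus probabilistic labels.

The module follows the Model/Results convention: build a :class:`LabelModel`
from a label matrix, call :meth:`~LabelModel.fit`, and read estimates,
diagnostics and posteriors off the returned :class:`LabelModelResults`.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np
import pandas as pd
from scipy.special import logsumexp

logger = logging.getLogger(__name__)

ABSTAIN = -1
_CLAMP_EPS = 0.01
_TIE_TOL = 1e-12

__all__ = [
    "LabelModelParams",
    "PosteriorLabels",
    "LabelModel",
    "LabelModelResults",
    "majority_vote",
    "mv_default_class",
    "estimate_accuracies_triplet",
    "fit_label_model",
    "posterior",
    "sweep_partitions",
]


def _values(label_matrix) -> np.ndarray:
    v = getattr(label_matrix, "values", label_matrix)
    return np.asarray(v, dtype=np.int64)


@dataclass
class LabelModelParams:
    """Per-source accuracies a_j in (1/K, 1), coverages c_j in [0, 1], and the
    class prior pi over classes 0..k."""

    accuracies: np.ndarray
    coverage: np.ndarray
    prior: np.ndarray
    k: int

    def __post_init__(self) -> None:
        self.accuracies = np.asarray(self.accuracies, dtype=float)
        self.coverage = np.asarray(self.coverage, dtype=float)
        self.prior = np.asarray(self.prior, dtype=float)
        K = self.k + 1
        if self.prior.shape != (K,) or abs(self.prior.sum() - 1.0) > 1e-9:
            raise ValueError("prior must be a length k+1 probability vector")
        if ((self.accuracies <= 0) | (self.accuracies >= 1)).any():
            raise ValueError("accuracies must lie in (0, 1)")
        if ((self.coverage < 0) | (self.coverage > 1)).any():
            raise ValueError("coverages must lie in [0, 1]")

    @property
    def m(self) -> int:
        return len(self.accuracies)


@dataclass
class PosteriorLabels:
    """Per-row class distributions with a hard label and an all-abstain flag."""

    probs: np.ndarray  # (n, k+1)
    hard: np.ndarray  # (n,)
    abstain: np.ndarray  # (n,) bool; True when every source abstained

    def __len__(self) -> int:
        return len(self.hard)

    def to_frame(self, word_index: Optional[Sequence[tuple[str, int]]] = None) -> pd.DataFrame:
        cols = {f"P{y}": self.probs[:, y] for y in range(self.probs.shape[1])}
        cols["hard"] = self.hard
        cols["abstain"] = self.abstain
        df = pd.DataFrame(cols)
        if word_index is not None:
            df.insert(0, "doc_id", [d for d, _ in word_index])
            df.insert(1, "word", [w for _, w in word_index])
        return df


# ---------------------------------------------------------------------------
# majority vote
# ---------------------------------------------------------------------------


def _vote_counts(values: np.ndarray, K: int) -> np.ndarray:
    return np.stack([(values == y).sum(axis=1) for y in range(K)], axis=1)


def mv_default_class(label_matrix, k: Optional[int] = None) -> int:
    """Corpus-wide most frequent majority-vote class, used as the tie/abstain
    default.  Rows whose own mode is ambiguous are excluded from the tally;
    an empty tally falls back to class 0."""
    values = _values(label_matrix)
    K = (k if k is not None else int(getattr(label_matrix, "k", values.max()))) + 1
    counts = _vote_counts(values, K)
    top = counts.max(axis=1)
    unique = (counts == top[:, None]).sum(axis=1) == 1
    ok = unique & (top > 0)
    if not ok.any():
        return 0
    tally = np.bincount(counts[ok].argmax(axis=1), minlength=K)
    return int(tally.argmax())


def majority_vote(label_matrix, default_class: int = 0, k: Optional[int] = None) -> PosteriorLabels:
    """Per-row modal non-abstain vote; ties and all-abstain rows default to
    ``default_class``.  Probability vectors are one-hot on the hard label."""
    values = _values(label_matrix)
    K = (k if k is not None else int(getattr(label_matrix, "k", max(values.max(), 0)))) + 1
    if not 0 <= default_class < K:
        raise ValueError(f"default_class {default_class} outside 0..{K - 1}")
    counts = _vote_counts(values, K)
    top = counts.max(axis=1)
    tie = (counts == top[:, None]).sum(axis=1) > 1
    hard = counts.argmax(axis=1)
    all_abstain = top == 0
    hard[tie | all_abstain] = default_class
    probs = np.zeros((len(hard), K))
    probs[np.arange(len(hard)), hard] = 1.0
    return PosteriorLabels(probs=probs, hard=hard, abstain=all_abstain)


# ---------------------------------------------------------------------------
# triplet accuracy recovery (binary tasks)
# ---------------------------------------------------------------------------


def estimate_accuracies_triplet(
    label_matrix, fallback: float = 0.7, clamp_eps: float = _CLAMP_EPS
) -> np.ndarray:
    """Closed-form accuracy recovery for binary (k=1) tasks.

    Votes are recoded to +/-1; for sources x, y the mean product over
    co-voting rows M_xy estimates the product of scaled accuracies
    a_x a_y with a = 2p - 1.  Each triplet (i, j, l) then gives
    |a_i| = sqrt(|M_ij M_il / M_jl|); per source we take the median over all
    usable triplets, resolve the sign positive (sources better than random),
    and map back to p = (a + 1) / 2, clamped to [0.5 + eps, 1 - eps].
    Sources with no usable triplet fall back to ``fallback`` with a warning.
    """
    values = _values(label_matrix)
    k = int(getattr(label_matrix, "k", 1))
    if k != 1:
        raise ValueError("triplet estimation requires a binary task (k=1)")
    n, m = values.shape
    if m < 3:
        raise ValueError("triplet estimation requires at least 3 sources")
    signed = np.where(values == ABSTAIN, 0.0, np.where(values == 1, 1.0, -1.0))
    votes = (values != ABSTAIN).astype(float)
    C = votes.T @ votes  # co-voting row counts
    S = signed.T @ signed
    with np.errstate(invalid="ignore"):
        M = np.where(C > 0, S / np.maximum(C, 1), np.nan)
    p = np.empty(m)
    for i in range(m):
        ests = []
        for j in range(m):
            if j == i:
                continue
            for l in range(j + 1, m):
                if l == i:
                    continue
                mij, mil, mjl = M[i, j], M[i, l], M[j, l]
                if np.isnan(mij) or np.isnan(mil) or np.isnan(mjl) or abs(mjl) < 1e-12:
                    continue
                ests.append(min(np.sqrt(abs(mij * mil / mjl)), 1.0))
        if ests:
            a = float(np.median(ests))
        else:
            logger.warning("source %d: no usable triplet; falling back to prior accuracy", i)
            a = 2.0 * fallback - 1.0
        p[i] = (a + 1.0) / 2.0
    return np.clip(p, 0.5 + clamp_eps, 1.0 - clamp_eps)


# ---------------------------------------------------------------------------
# label model (Model / Results)
# ---------------------------------------------------------------------------


def _log_joint(values: np.ndarray, params: LabelModelParams) -> np.ndarray:
    """(n, K) unnormalized log posterior: log pi_y + sum over voting sources of
    log a_j if the vote equals y, else log((1 - a_j)/k)."""
    n, m = values.shape
    K = params.k + 1
    logp = np.tile(np.log(params.prior), (n, 1))
    log_a = np.log(params.accuracies)
    log_w = np.log((1.0 - params.accuracies) / max(params.k, 1))
    ys = np.arange(K)
    for j in range(m):
        col = values[:, j]
        voting = col != ABSTAIN
        if not voting.any():
            continue
        contrib = np.where(col[voting, None] == ys[None, :], log_a[j], log_w[j])
        logp[voting] += contrib
    return logp


class LabelModel:
    """Generative model of a label matrix under conditional independence.

    Parameters
    ----------
    label_matrix : LabelMatrix or (n, m) integer array
        Votes in {-1, 0..k}; -1 is abstain.
    k : int, optional
        Highest class index; required for plain arrays without a ``k``
        attribute.
    """

    def __init__(self, label_matrix, k: Optional[int] = None):
        self.values = _values(label_matrix)
        if self.values.ndim != 2:
            raise ValueError("label matrix must be 2-D (rows x sources)")
        inferred = getattr(label_matrix, "k", None)
        self.k = int(k if k is not None else (inferred if inferred is not None else max(self.values.max(), 1)))
        self.word_index = getattr(label_matrix, "word_index", None)
        self.source_names = list(
            getattr(label_matrix, "source_names", None)
            or [f"source_{j}" for j in range(self.values.shape[1])]
        )
        self.n, self.m = self.values.shape

    def fit(
        self,
        init_prior: float = 0.7,
        max_iter: int = 500,
        tol: float = 1e-6,
        l2: float = 0.0,
        seed: Optional[int] = None,
        use_triplet_init: bool = True,
    ) -> "LabelModelResults":
        """EM on the marginal likelihood of the label matrix.

        Accuracies start at the uniform accuracy prior ``init_prior`` (for
        binary tasks the closed-form triplet estimates override the
        initialization when computable); the class prior starts from
        majority-vote frequencies.  ``l2`` acts as a pseudo-count pull of each
        accuracy toward ``init_prior``.  The fit is deterministic; ``seed`` is
        accepted for interface symmetry with stochastic trainers.
        """
        if self.m < 3:
            raise ValueError(
                "label model requires at least 3 sources: accuracies are not "
                "identifiable from agreement rates below that"
            )
        voting_rows = (self.values != ABSTAIN).any(axis=1)
        if not voting_rows.any():
            raise ValueError("degenerate label matrix: every source abstains on every row")
        K = self.k + 1
        lo, hi = 1.0 / K + _CLAMP_EPS, 1.0 - _CLAMP_EPS

        acc = np.full(self.m, float(init_prior))
        triplet_init = None
        if self.k == 1 and use_triplet_init:
            try:
                triplet_init = estimate_accuracies_triplet(self, fallback=init_prior)
                acc = triplet_init.copy()
            except ValueError:
                pass
        acc = np.clip(acc, lo, hi)

        nonabstain = self.values[self.values != ABSTAIN]
        overall_mode = int(np.bincount(nonabstain, minlength=K).argmax())
        mv = majority_vote(self.values, default_class=overall_mode, k=self.k)
        prior = np.bincount(mv.hard, minlength=K).astype(float)
        prior = np.maximum(prior, 1e-3)
        prior /= prior.sum()

        coverage = (self.values != ABSTAIN).mean(axis=0)
        votes_per_source = (self.values != ABSTAIN).sum(axis=0).astype(float)

        ll_prev = -np.inf
        history: list[float] = []
        converged = False
        n_iter = 0
        for n_iter in range(1, max_iter + 1):
            params = LabelModelParams(accuracies=acc, coverage=coverage, prior=prior, k=self.k)
            logp = _log_joint(self.values, params)
            ll_rows = logsumexp(logp, axis=1)
            gamma = np.exp(logp - ll_rows[:, None])
            ll = float(ll_rows.sum())
            history.append(ll)

            # M-step: expected correct-vote fraction per source, prior from voting rows
            correct = np.zeros(self.m)
            for j in range(self.m):
                col = self.values[:, j]
                v = col != ABSTAIN
                if v.any():
                    correct[j] = gamma[v, col[v]].sum()
            acc = (correct + l2 * init_prior) / np.maximum(votes_per_source + l2, 1e-12)
            acc = np.clip(acc, lo, hi)
            prior = gamma[voting_rows].mean(axis=0)
            prior = np.maximum(prior, 1e-6)
            prior /= prior.sum()

            if ll - ll_prev < tol and n_iter > 1:
                converged = True
                break
            ll_prev = ll

        params = LabelModelParams(accuracies=acc, coverage=coverage, prior=prior, k=self.k)
        return LabelModelResults(
            model=self,
            params=params,
            converged=converged,
            n_iter=n_iter,
            loglike=history[-1],
            loglike_history=history,
            triplet_init=triplet_init,
        )


@dataclass
class LabelModelResults:
    """Fitted label model: estimates, diagnostics, and posterior inference."""

    model: LabelModel
    params: LabelModelParams
    converged: bool
    n_iter: int
    loglike: float
    loglike_history: list[float] = field(default_factory=list)
    triplet_init: Optional[np.ndarray] = None

    @property
    def accuracies(self) -> pd.Series:
        return pd.Series(self.params.accuracies, index=self.model.source_names, name="accuracy")

    @property
    def coverage(self) -> pd.Series:
        return pd.Series(self.params.coverage, index=self.model.source_names, name="coverage")

    @property
    def prior(self) -> np.ndarray:
        return self.params.prior

    def predict_proba(self, label_matrix=None, default_class: Optional[int] = None) -> PosteriorLabels:
        values = self.model.values if label_matrix is None else _values(label_matrix)
        if default_class is None:
            default_class = mv_default_class(values, k=self.params.k)
        return posterior(values, self.params, default_class=default_class)

    def predict(self, label_matrix=None, default_class: Optional[int] = None) -> np.ndarray:
        return self.predict_proba(label_matrix, default_class).hard

    def summary(self) -> str:
        df = pd.DataFrame(
            {
                "accuracy": self.params.accuracies,
                "coverage": self.params.coverage,
            },
            index=self.model.source_names,
        )
        if self.triplet_init is not None:
            df["triplet_init"] = self.triplet_init
        prior = ", ".join(f"P({y})={p:.3f}" for y, p in enumerate(self.params.prior))
        lines = [
            "Label model (conditional-independence accuracy model, EM)",
            f"rows: {self.model.n}   sources: {self.model.m}   classes: 0..{self.params.k}",
            f"log-likelihood: {self.loglike:.3f}   iterations: {self.n_iter}"
            f"   converged: {self.converged}",
            f"class prior: {prior}",
            "",
            df.round(4).to_string(),
        ]
        return "\n".join(lines)


def fit_label_model(
    label_matrix,
    k: Optional[int] = None,
    init_prior: float = 0.7,
    max_iter: int = 500,
    tol: float = 1e-6,
    l2: float = 0.0,
    seed: Optional[int] = None,
) -> LabelModelParams:
    """Functional wrapper: fit and return only the parameters."""
    return LabelModel(label_matrix, k=k).fit(
        init_prior=init_prior, max_iter=max_iter, tol=tol, l2=l2, seed=seed
    ).params


def posterior(label_matrix, params: LabelModelParams, default_class: int = 0) -> PosteriorLabels:
    """P(y | row) under the fitted model: proportional to pi_y times, over
    voting sources, a_j if the vote equals y else (1 - a_j)/k.  All-abstain
    rows return the prior and are flagged; hard labels are the argmax with
    exact ties going to ``default_class``."""
    values = _values(label_matrix)
    logp = _log_joint(values, params)
    probs = np.exp(logp - logsumexp(logp, axis=1)[:, None])
    all_abstain = (values == ABSTAIN).all(axis=1)
    hard = probs.argmax(axis=1)
    top = probs.max(axis=1)
    tie = (probs >= top[:, None] - _TIE_TOL).sum(axis=1) > 1
    hard[tie] = default_class
    return PosteriorLabels(probs=probs, hard=hard, abstain=all_abstain)


def _mv_equivalent_params(m: int, k: int, init_prior: float = 0.7) -> LabelModelParams:
    """Degenerate fallback for m < 3: equal accuracies and a uniform prior
    make the posterior argmax provably identical to majority vote."""
    K = k + 1
    return LabelModelParams(
        accuracies=np.full(m, np.clip(init_prior, 1.0 / K + _CLAMP_EPS, 1 - _CLAMP_EPS)),
        coverage=np.ones(m),
        prior=np.full(K, 1.0 / K),
        k=k,
    )


# ---------------------------------------------------------------------------
# partition sweep
# ---------------------------------------------------------------------------


def sweep_partitions(
    corpus,
    ranked_terminologies,
    fixed_lfs,
    s_values: Sequence[int],
    gold_spans,
    k: int = 1,
    include_merged_remainder: bool = True,
    init_prior: float = 0.7,
    l2: float = 0.0,
    seed: Optional[int] = None,
    return_details: bool = False,
):
    """Sweep the terminology partition size s: for each s build the top-s
    sources plus merged remainder, apply them (plus any fixed LFs), aggregate
    by majority vote and by the label model, and score exact-span F1 against
    gold.  Scores are also reported relative to the best majority-vote score
    over the sweep.  Partitions yielding fewer than 3 sources use the
    MV-equivalent degenerate parameters (accuracies are unidentifiable there).
    """
    from .evaluation import exact_span_prf, word_predictions_to_spans
    from .labeling import build_label_matrix, semantic_type_lf
    from .ontology import PartitionConfig, partition_terminologies

    rows = []
    details = {}
    for s in s_values:
        sources = partition_terminologies(
            ranked_terminologies, PartitionConfig(s=s, include_merged_remainder=include_merged_remainder)
        )
        lfs = [semantic_type_lf(t) for t in sources] + list(fixed_lfs)
        L = build_label_matrix(lfs, corpus, k=k)
        default = mv_default_class(L)
        mv = majority_vote(L, default_class=default)
        if L.m >= 3:
            res = LabelModel(L).fit(init_prior=init_prior, l2=l2, seed=seed)
            lm = res.predict_proba(default_class=default)
        else:
            lm = posterior(L, _mv_equivalent_params(L.m, k, init_prior), default_class=default)
        mv_spans = word_predictions_to_spans(corpus, mv.hard)
        lm_spans = word_predictions_to_spans(corpus, lm.hard)
        mv_f1 = exact_span_prf(gold_spans, mv_spans).f1
        lm_f1 = exact_span_prf(gold_spans, lm_spans).f1
        rows.append({"s": s, "m": L.m, "mv_f1": mv_f1, "lm_f1": lm_f1})
        if return_details:
            details[s] = {"matrix": L, "mv": mv, "lm": lm}
    table = pd.DataFrame(rows)
    best_mv = table["mv_f1"].max()
    table["mv_delta"] = table["mv_f1"] - best_mv
    table["lm_delta"] = table["lm_f1"] - best_mv
    return (table, details) if return_details else table
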