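"""Model-agnostic Shapley-value token attribution.

A sequence classifier is treated as a cooperative game over its tokens:
the value of a coalition S is the positive-class logit when only the
tokens in S are visible and every other token is replaced by the mask
symbol (the all-mask pattern is the baseline).  Each token's Shapley value
is its average marginal contribution over orderings, which distributes
``f(full) - f(all-masked)`` fairly across tokens (local accuracy).

``kernel_shap`` estimates the values with the Shapley-kernel weighted
least squares of Lundberg & Lee's KernelExplainer: sampled (or, for small
J, fully enumerated) coalitions are fit by a linear model under the
constraint that attributions sum to ``f(full) - f(empty)``.
``exact_shapley`` is the brute-force enumeration oracle for small J.

Per-unique-token summaries (mean, mean absolute value, sd, count and the
normal-approximation 95% CI ``1.96 * sd / sqrt(n)``) and frequency/mean/
absolute-mean rankings cross-validate the attention-derived motifs: tokens
the attention pipeline flags should also carry positive SHAP mass.
"""

from __future__ import annotations

from dataclasses import dataclass
from itertools import combinations
from math import comb, factorial
from typing import Callable, Sequence

import numpy as np
import pandas as pd

Scorer = Callable[[np.ndarray], float]
"""Black-box positive-logit function of a boolean keep-mask over tokens."""


@dataclass(frozen=True)
class TokenAttribution:
    sequence_id: str
    token_text: str
    position: int
    shap_value: float


# ---------------------------------------------------------------------------
# Exact Shapley oracle
# ---------------------------------------------------------------------------

def exact_shapley(
    scorer: Scorer, tokens: Sequence[str], sequence_id: str = ""
) -> list[TokenAttribution]:
    """Exact Shapley values by coalition enumeration (J <= 12).

    phi_j = sum over S not containing j of
    |S|! (J - |S| - 1)! / J! * (f(S + j) - f(S)).
    """
    J = len(tokens)
    if J > 12:
        raise ValueError(f"exact enumeration refused for J={J} > 12")
    values: dict[frozenset, float] = {}
    for r in range(J + 1):
        for S in combinations(range(J), r):
            mask = np.zeros(J, dtype=bool)
            mask[list(S)] = True
            values[frozenset(S)] = float(scorer(mask))
    out = []
    for j in range(J):
        phi = 0.0
        others = [i for i in range(J) if i != j]
        for r in range(J):
            w = factorial(r) * factorial(J - r - 1) / factorial(J)
            for S in combinations(others, r):
                fs = frozenset(S)
                phi += w * (values[fs | {j}] - values[fs])
        out.append(TokenAttribution(sequence_id, tokens[j], j, phi))
    return out


# ---------------------------------------------------------------------------
# Kernel SHAP
# ---------------------------------------------------------------------------

def _shapley_kernel_weight(J: int, s: int) -> float:
    # weight of a coalition of size s (0 < s < J); endpoints get infinite
    # weight and are handled by the sum constraint instead
    return (J - 1) / (comb(J, s) * s * (J - s))


def kernel_shap(
    scorer: Scorer,
    tokens: Sequence[str],
    n_coalitions: int = 2048,
    seed: int = 0,
    sequence_id: str = "",
) -> list[TokenAttribution]:
    """Kernel SHAP estimate of per-token attributions.

    Coalitions are weighted by the Shapley kernel
    ``(J-1) / (C(J,s) * s * (J-s))`` and fit by weighted least squares with
    the local-accuracy constraint ``sum(phi) = f(full) - f(empty)``
    eliminated analytically.  When ``2^J - 2`` does not exceed
    ``n_coalitions`` every proper coalition is enumerated and the estimate
    is exact (equals :func:`exact_shapley`); otherwise coalitions are
    sampled by kernel-implied size weights, deterministically under
    ``seed``.
    """
    J = len(tokens)
    if J == 0:
        raise ValueError("no tokens")
    f_empty = float(scorer(np.zeros(J, dtype=bool)))
    f_full = float(scorer(np.ones(J, dtype=bool)))
    if J == 1:
        return [TokenAttribution(sequence_id, tokens[0], 0, f_full - f_empty)]
    if n_coalitions < 2 * J + 2:
        raise ValueError(f"n_coalitions must be >= {2 * J + 2}")

    interior = 2**J - 2 if J <= 30 else np.inf
    if interior <= n_coalitions:
        masks = []
        for r in range(1, J):
            for S in combinations(range(J), r):
                m = np.zeros(J, dtype=bool)
                m[list(S)] = True
                masks.append(m)
        Z = np.array(masks)
        w = np.array([_shapley_kernel_weight(J, int(m.sum())) for m in Z])
    else:
        rng = np.random.default_rng(seed)
        sizes = np.arange(1, J)
        size_p = np.array([(J - 1) / (s * (J - s)) for s in sizes])
        size_p /= size_p.sum()
        Z = np.zeros((n_coalitions, J), dtype=bool)
        for i in range(n_coalitions):
            s = int(rng.choice(sizes, p=size_p))
            idx = rng.choice(J, size=s, replace=False)
            Z[i, idx] = True
        # kernel weight already reflected in the size distribution; the
        # remaining per-sample weight is uniform over coalitions of a size
        w = np.ones(n_coalitions)

    y = np.array([scorer(m) for m in Z], dtype=float) - f_empty
    total = f_full - f_empty
    # eliminate phi_J via the constraint sum(phi) = total
    Zf = Z.astype(float)
    A = Zf[:, :-1] - Zf[:, [-1]]
    b = y - Zf[:, -1] * total
    W = np.diag(w)
    lhs = A.T @ W @ A
    rhs = A.T @ W @ b
    phi_head = np.linalg.lstsq(lhs, rhs, rcond=None)[0]
    phi = np.append(phi_head, total - phi_head.sum())
    return [TokenAttribution(sequence_id, tokens[j], j, float(phi[j]))
            for j in range(J)]


def attribute_records(
    provider,
    records,
    n_coalitions: int = 2048,
    seed: int = 0,
) -> list[TokenAttribution]:
    """Kernel-SHAP attributions for every record of a dataset.

    ``provider`` must expose ``tokenize`` and ``masked_logit(seq_id,
    sequence, keep)`` (the all-mask baseline scorer contract).
    """
    out: list[TokenAttribution] = []
    for i, rec in enumerate(records):
        spans = provider.tokenize(rec.sequence)
        tokens = [sp.token_text for sp in spans]

        def scorer(keep, _rec=rec):
            return provider.masked_logit(_rec.transcript_id, _rec.sequence, keep)

        out.extend(kernel_shap(scorer, tokens, n_coalitions=n_coalitions,
                               seed=seed + i, sequence_id=rec.transcript_id))
    return out


# ---------------------------------------------------------------------------
# Summaries and ranking
# ---------------------------------------------------------------------------

def summarize_tokens(
    attributions: Sequence[TokenAttribution], min_count: int = 5
) -> pd.DataFrame:
    """Per-unique-token summary statistics across all sequences.

    Columns: token, n, mean_shap, abs_mean_shap (mean of |values|, the
    usual SHAP importance), mean_abs_shap_signed (|mean|, the other reading
    of "absolute mean"), sd (sample), ci_half_width = 1.96 * sd / sqrt(n).
    Tokens occurring fewer than ``min_count`` times are excluded as noise.
    """
    if min_count < 2:
        raise ValueError("min_count must be >= 2")
    if not attributions:
        return pd.DataFrame(columns=[
            "token", "n", "mean_shap", "abs_mean_shap",
            "mean_abs_shap_signed", "sd", "ci_half_width"])
    df = pd.DataFrame([
        {"token": a.token_text, "value": a.shap_value} for a in attributions
    ])
    g = df.groupby("token")["value"]
    summary = pd.DataFrame({
        "n": g.size(),
        "mean_shap": g.mean(),
        "abs_mean_shap": g.apply(lambda v: v.abs().mean()),
        "sd": g.std(ddof=1),
    })
    summary["mean_abs_shap_signed"] = summary["mean_shap"].abs()
    summary = summary[summary["n"] >= min_count].reset_index()
    summary["sd"] = summary["sd"].fillna(0.0)
    summary["ci_half_width"] = 1.96 * summary["sd"] / np.sqrt(summary["n"])
    return summary[["token", "n", "mean_shap", "abs_mean_shap",
                    "mean_abs_shap_signed", "sd", "ci_half_width"]]


def rank_tokens(
    summary: pd.DataFrame, by: str = "abs_mean", top_k: int = 20
) -> dict[str, pd.DataFrame]:
    """Rank tokens and split the top-k into positive/negative contributors.

    ``by`` is one of ``frequency`` (occurrence count), ``mean`` (mean SHAP)
    or ``abs_mean`` (mean absolute SHAP).  Sorting is descending on the key
    with lexicographic token tie-break, so permuting the input rows cannot
    change the result.
    """
    keys = {"frequency": "n", "mean": "mean_shap", "abs_mean": "abs_mean_shap"}
    if by not in keys:
        raise ValueError(f"rank key must be one of {sorted(keys)}")
    if top_k < 1:
        raise ValueError("top_k must be >= 1")
    ranked = summary.sort_values(
        [keys[by], "token"], ascending=[False, True], kind="mergesort"
    ).head(top_k)
    return {
        "ranked": ranked.reset_index(drop=True),
        "top_positive": ranked[ranked["mean_shap"] > 0].reset_index(drop=True),
        "top_negative": ranked[ranked["mean_shap"] < 0].reset_index(drop=True),
    }
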