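"""Connection scores: per-instance, diminished, and treatment-set level.

The connection score of a profile ``R`` against a signature ``s`` is the
signed-rank sum over the signature probes, normalized by the largest sum
any ``m``-probe signature could attain::

    c(R, s) = sum_i R(g_i) s(g_i) / sum_{i=1..m} (N - i + 1)

so ``c`` lies in ``[-1, 1]``, with ``+1`` meaning the signature probes
occupy the top-m absolute ranks with fully concordant signs (a perfect
mimic) and ``-1`` a perfect reversal.  Treatment-set scores aggregate the
member instance scores by the median, which is robust to the outlying
instances commonly seen inside real treatment sets.

Numerators are exact integers; the division is the only floating-point
step, so instance scores are exactly reproducible as integer ratios.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import TYPE_CHECKING, Sequence

import numpy as np

from .refdb import GroupBy, ReferenceProfile, TreatmentSetKey
from .signatures import QuerySignature

if TYPE_CHECKING:  # pragma: no cover
    from .refdb import ReferenceDatabase


@dataclass(frozen=True)
class InstanceScore:
    instance_id: str
    score: float


@dataclass(frozen=True)
class SetScore:
    set_key: TreatmentSetKey | None
    score: float
    set_size: int


def max_denominator(m: int, N: int) -> int:
    """``N + (N-1) + ... + (N-m+1)``: the maximal m-probe signed-rank sum."""
    if not (1 <= m <= N):
        raise ValueError(f"need 1 <= m <= N, got m={m}, N={N}")
    return m * N - m * (m - 1) // 2


def signature_index_arrays(
    sig: QuerySignature, probe_index
) -> tuple[np.ndarray, np.ndarray]:
    """Positions of the signature's up and down probes in the probe order.

    Raises if any probe is absent, i.e. the signature was not reconciled.
    """
    try:
        up = np.array([probe_index[p] for p in sig.up], dtype=np.intp)
        down = np.array([probe_index[p] for p in sig.down], dtype=np.intp)
    except KeyError as exc:
        raise ValueError(
            f"signature {sig.name!r} is not reconciled with the database: "
            f"unknown probe {exc.args[0]!r}"
        ) from None
    return up, down


def _numerator(ranks: np.ndarray, up_idx: np.ndarray, down_idx: np.ndarray) -> int:
    total = 0
    if up_idx.size:
        total += int(ranks[up_idx].sum())
    if down_idx.size:
        total -= int(ranks[down_idx].sum())
    return total


def connection_score(profile: ReferenceProfile, sig: QuerySignature) -> InstanceScore:
    """Connection score of one reference profile against a signature."""
    up_idx, down_idx = signature_index_arrays(sig, profile.probe_index)
    denom = max_denominator(sig.m, profile.n_probes)
    num = _numerator(profile.signed_ranks, up_idx, down_idx)
    return InstanceScore(profile.instance_id, num / denom)


def diminished_score(
    profile: ReferenceProfile, sig: QuerySignature, k: str
) -> float:
    """Connection score with probe ``k``'s term removed from the numerator.

    The denominator is unchanged (still over all m signature probes), so
    ``c - c*_k = R(k) s(k) / denominator`` holds identically.
    """
    if k not in sig.up and k not in sig.down:
        raise ValueError(f"probe {k!r} is not in signature {sig.name!r}")
    up_idx, down_idx = signature_index_arrays(sig, profile.probe_index)
    denom = max_denominator(sig.m, profile.n_probes)
    num = _numerator(profile.signed_ranks, up_idx, down_idx)
    k_term = int(profile.signed_ranks[profile.probe_index[k]]) * sig.sign(k)
    return (num - k_term) / denom


def set_score(
    scores: Sequence[InstanceScore | float], set_key: TreatmentSetKey | None = None
) -> SetScore:
    """Median of the member instance scores.

    For an even member count the median is the arithmetic mean of the two
    middle values, which preserves the antisymmetry of the scores under
    signature flips.
    """
    if len(scores) == 0:
        raise ValueError("cannot aggregate an empty score list")
    values = np.array(
        [s.score if isinstance(s, InstanceScore) else float(s) for s in scores]
    )
    return SetScore(set_key, float(np.median(values)), len(values))


def instance_scores_matrix(
    ranks: np.ndarray, up_idx: np.ndarray, down_idx: np.ndarray, denom: int
) -> np.ndarray:
    """Scores of every profile row in ``ranks`` for one signature."""
    num = np.zeros(ranks.shape[0], dtype=np.int64)
    if up_idx.size:
        num += ranks[:, up_idx].sum(axis=1, dtype=np.int64)
    if down_idx.size:
        num -= ranks[:, down_idx].sum(axis=1, dtype=np.int64)
    return num / denom


def batch_set_scores(
    ranks: np.ndarray,
    up_mat: np.ndarray,
    down_mat: np.ndarray,
    denom: int,
) -> np.ndarray:
    """Median set scores of one instance set against many signatures.

    ``ranks`` is the (k, N) rank matrix of the set members; ``up_mat`` and
    ``down_mat`` are (n, m_up) / (n, m_down) probe-index matrices, one row
    per signature.  Returns the n median-aggregated set scores.
    """
    n = up_mat.shape[0] if up_mat.size else down_mat.shape[0]
    num = np.zeros((ranks.shape[0], n), dtype=np.int64)
    if up_mat.size:
        num += ranks[:, up_mat].sum(axis=2, dtype=np.int64)
    if down_mat.size:
        num -= ranks[:, down_mat].sum(axis=2, dtype=np.int64)
    return np.median(num / denom, axis=0)


def score_all_sets(
    db: "ReferenceDatabase", sig: QuerySignature, mode: GroupBy
) -> list[SetScore]:
    """One median-aggregated SetScore per treatment set, sorted by key.

    Per-set evaluation is independent and order-free; the output ordering
    is fixed by the set key so results are deterministic.
    """
    up_idx, down_idx = signature_index_arrays(sig, db.probe_index)
    denom = max_denominator(sig.m, db.n_probes)
    out = []
    for key, members in db.group_sets(mode).items():
        rows = db.rows_for(members)
        scores = instance_scores_matrix(db.ranks[rows], up_idx, down_idx, denom)
        out.append(SetScore(key, float(np.median(scores)), len(members)))
    return out
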