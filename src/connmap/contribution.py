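"""Contribution Fractions: per-probe attribution of set connections.

The influence of one signature probe on a treatment-set connection is
measured by removing its term from the score numerator (the "diminished
score" ``c*_k``, denominator unchanged) and comparing medians over the
set's instances:

    CF_k = 1 - median(c*_k) / median(c)

Within each set the fractions are normalized by the largest one, so the
probe contributing most to the connection has ``CF*_k = 1.0`` exactly.
Probes whose terms oppose the connection get negative CF; the sign is
retained through normalization (division by the positive maximum).
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path
from typing import TYPE_CHECKING, Mapping, Sequence

import numpy as np
import pandas as pd

from .refdb import GroupBy, TreatmentSetKey
from .scoring import instance_scores_matrix, max_denominator, signature_index_arrays
from .significance import ConnectionResult
from .signatures import QuerySignature

if TYPE_CHECKING:  # pragma: no cover
    from .refdb import ReferenceDatabase


@dataclass(frozen=True)
class ContributionRecord:
    set_key: TreatmentSetKey
    probe_id: str
    cf: float
    cf_norm: float


def contribution_fractions(
    db: "ReferenceDatabase",
    instance_ids: Sequence[str],
    sig: QuerySignature,
) -> dict[str, float]:
    """CF_k for every signature probe over one treatment set.

    The full-score and diminished-score medians are taken independently
    over the set's instances.  Raises if the median set score is zero,
    where the ratio is undefined.
    """
    up_idx, down_idx = signature_index_arrays(sig, db.probe_index)
    denom = max_denominator(sig.m, db.n_probes)
    rows = db.rows_for(instance_ids)
    ranks = db.ranks[rows]
    full = instance_scores_matrix(ranks, up_idx, down_idx, denom)
    med_full = float(np.median(full))
    if med_full == 0.0:
        raise ValueError(
            "median set score is 0; the contribution fraction is undefined"
        )
    # c*_k per instance = c - R(k)s(k)/denom, for all k at once
    sig_idx = np.concatenate([up_idx, down_idx])
    signs = np.concatenate([np.ones(len(up_idx)), -np.ones(len(down_idx))])
    terms = ranks[:, sig_idx] * signs / denom  # (k_instances, m)
    diminished = full[:, None] - terms
    med_dim = np.median(diminished, axis=0)
    cfs = 1.0 - med_dim / med_full
    return {p: float(v) for p, v in zip(sig.probes, cfs)}


def contribution_fraction(
    db: "ReferenceDatabase",
    instance_ids: Sequence[str],
    sig: QuerySignature,
    k: str,
) -> float:
    """CF of a single probe ``k`` over one treatment set."""
    if k not in sig.up and k not in sig.down:
        raise ValueError(f"probe {k!r} is not in signature {sig.name!r}")
    return contribution_fractions(db, instance_ids, sig)[k]


def normalize_contributions(cfs: Mapping[str, float]) -> dict[str, float]:
    """``CF*_k = CF_k / max_k CF_k``; the top contributor becomes exactly 1.

    Negative fractions stay negative (they are divided by the positive
    maximum, not its absolute value).
    """
    if not cfs:
        raise ValueError("no contribution fractions to normalize")
    top = max(cfs.values())
    if top <= 0.0:
        raise ValueError("all contribution fractions are <= 0; cannot normalize")
    return {k: v / top for k, v in cfs.items()}


def contribution_matrix(
    db: "ReferenceDatabase",
    sig: QuerySignature,
    results: Sequence[ConnectionResult],
    mode: GroupBy = GroupBy.DRUG_AND_CELL_LINE,
    top_n: int = 100,
    row_sort: str = "median",
) -> pd.DataFrame:
    """Normalized CF matrix: signature probes x top connections.

    Connections are ranked by ``|Z|`` and at most ``top_n`` retained;
    columns are ordered alphabetically by set label.  Rows follow the
    signature order, or descending median CF* when ``row_sort="median"``.
    """
    if not results:
        raise ValueError("no connection results supplied")
    if row_sort not in ("median", "signature"):
        raise ValueError(f"unknown row_sort {row_sort!r}")
    ranked = sorted(results, key=lambda r: (-abs(r.z), r.set_key.sort_key))[:top_n]
    sets = db.group_sets(mode)
    columns: dict[str, dict[str, float]] = {}
    for r in ranked:
        cfs = contribution_fractions(db, sets[r.set_key], sig)
        columns[r.set_key.label] = normalize_contributions(cfs)
    frame = pd.DataFrame(columns, index=list(sig.probes))
    frame = frame.reindex(sorted(frame.columns), axis=1)
    if row_sort == "median":
        order = frame.median(axis=1).sort_values(ascending=False).index
        frame = frame.loc[order]
    frame.index.name = "probe_id"
    return frame


def write_contribution_csv(matrix: pd.DataFrame, path: str | Path) -> None:
    """Spreadsheet-ready CSV: probe_id first, one column per set, 6 d.p."""
    matrix.to_csv(path, float_format="%.6f")
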