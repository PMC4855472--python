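"""Signed-rank reference databases for gene-expression connectivity mapping.

A reference database holds one *reference profile* per perturbation
instance (one compound applied to one cell line at one dose/time).  Each
profile encodes the instance's differential expression — treated values
minus the aggregate of the controls on the same plate — as signed ranks:
the probe with the largest absolute differential receives absolute rank
``N`` (the number of probes), the smallest receives rank 1, and each rank
carries the sign of the underlying differential.  The absolute ranks of a
profile therefore always form the exact set ``{1, ..., N}``.

The on-disk layout is a plain-text directory::

    probes.txt     one probe identifier per line (order-defining)
    ranks.tsv.gz   instances x N signed integers, first column instance_id
    instances.tsv  metadata (instance_id, perturbagen, cell_line, dose,
                   time, plate_id)
"""

from __future__ import annotations

import gzip
import logging
from dataclasses import dataclass, field
from enum import Enum
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

log = logging.getLogger(__name__)

#: metadata columns stored for every profile, in file order
META_COLUMNS = ("instance_id", "perturbagen", "cell_line", "dose", "time", "plate_id")


class GroupBy(str, Enum):
    """How instances are grouped into treatment sets."""

    DRUG = "drug"
    DRUG_AND_CELL_LINE = "drug_cell_line"


@dataclass(frozen=True)
class TreatmentSetKey:
    """Identity of a treatment set: a perturbagen, optionally with a cell line.

    ``cell_line`` is ``None`` when grouping by drug across all cell lines.
    Key equality is exact string equality on the defined fields.
    """

    perturbagen: str
    cell_line: str | None = None

    @property
    def label(self) -> str:
        if self.cell_line is None:
            return self.perturbagen
        return f"{self.perturbagen}|{self.cell_line}"

    @property
    def sort_key(self) -> tuple[str, str]:
        return (self.perturbagen, self.cell_line if self.cell_line is not None else "")


@dataclass
class ExpressionInstance:
    """One experiment instance: N platform-normalized expression values."""

    instance_id: str
    values: np.ndarray
    plate_id: str
    perturbagen: str
    cell_line: str
    dose: str = ""
    time: str = ""
    is_control: bool = False

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        if self.values.ndim != 1:
            raise ValueError(
                f"instance {self.instance_id!r}: values must be a 1-D vector"
            )
        if not np.all(np.isfinite(self.values)):
            raise ValueError(
                f"instance {self.instance_id!r}: values contain NaN/Inf entries"
            )


@dataclass
class ReferenceProfile:
    """Signed ranks of one instance, plus its metadata.

    ``probe_index`` maps probe id -> position, shared with the owning
    database so that profiles can be scored without copying the probe list.
    """

    instance_id: str
    signed_ranks: np.ndarray
    metadata: dict[str, str]
    probe_index: Mapping[str, int] = field(repr=False, default_factory=dict)

    @property
    def n_probes(self) -> int:
        return self.signed_ranks.size

    def rank_of(self, probe_id: str) -> int:
        return int(self.signed_ranks[self.probe_index[probe_id]])


def differential_profile(
    treated: ExpressionInstance,
    controls: Sequence[ExpressionInstance],
    aggregate: str = "mean",
) -> np.ndarray:
    """Differential expression of ``treated`` against its same-plate controls.

    Returns ``d`` with ``d[g] = treated.values[g] - agg_g(controls)`` where the
    aggregate is the per-probe mean (default) or median of the control values.
    """
    if len(controls) == 0:
        raise ValueError(
            f"no controls supplied for instance {treated.instance_id!r} "
            f"on plate {treated.plate_id!r}"
        )
    for c in controls:
        if c.plate_id != treated.plate_id:
            raise ValueError(
                f"control {c.instance_id!r} is on plate {c.plate_id!r} but "
                f"treated instance {treated.instance_id!r} is on plate "
                f"{treated.plate_id!r}"
            )
        if c.values.size != treated.values.size:
            raise ValueError(
                f"control {c.instance_id!r} has {c.values.size} values, "
                f"expected {treated.values.size}"
            )
    ctl = np.vstack([c.values for c in controls])
    if aggregate == "mean":
        baseline = ctl.mean(axis=0)
    elif aggregate == "median":
        baseline = np.median(ctl, axis=0)
    else:
        raise ValueError(f"unknown control aggregate {aggregate!r}")
    return treated.values - baseline


def signed_rank(d: np.ndarray) -> np.ndarray:
    """Signed-rank transform of a differential expression vector.

    The probe with the i-th smallest ``|d|`` receives absolute rank ``i``
    (the largest gets ``N``) and each rank carries ``sign(d)``.  Ties in
    ``|d|`` are broken by ascending probe index so the result is always an
    exact signed permutation of ``1..N``; ``sign(0)`` is taken as ``+``.
    """
    d = np.asarray(d, dtype=float)
    if d.ndim != 1 or d.size < 1:
        raise ValueError("d must be a non-empty 1-D vector")
    n = d.size
    order = np.argsort(np.abs(d), kind="stable")
    ranks = np.empty(n, dtype=np.int32)
    ranks[order] = np.arange(1, n + 1, dtype=np.int32)
    signs = np.where(d < 0, -1, 1).astype(np.int32)
    return signs * ranks


class ReferenceDatabase:
    """An ordered probe universe plus one signed-rank profile per instance."""

    def __init__(
        self,
        probe_ids: Sequence[str],
        ranks: np.ndarray,
        meta: pd.DataFrame,
    ) -> None:
        probe_ids = list(probe_ids)
        if len(set(probe_ids)) != len(probe_ids):
            raise ValueError("probe_ids contain duplicates")
        ranks = np.asarray(ranks, dtype=np.int32)
        if ranks.ndim != 2 or ranks.shape[1] != len(probe_ids):
            raise ValueError(
                f"ranks must be (n_profiles, {len(probe_ids)}); got {ranks.shape}"
            )
        missing = set(META_COLUMNS) - set(meta.columns)
        if missing:
            raise ValueError(f"metadata is missing columns {sorted(missing)}")
        if ranks.shape[0] != len(meta):
            raise ValueError("metadata row count does not match rank matrix")
        if meta["instance_id"].duplicated().any():
            dups = meta.loc[meta["instance_id"].duplicated(), "instance_id"]
            raise ValueError(f"duplicate instance ids: {sorted(set(dups))}")
        self.probe_ids = probe_ids
        self.ranks = ranks
        self.meta = meta.reset_index(drop=True)
        self._probe_index: dict[str, int] = {p: i for i, p in enumerate(probe_ids)}
        self._row_index: dict[str, int] = {
            iid: i for i, iid in enumerate(self.meta["instance_id"])
        }

    # -- basic accessors -------------------------------------------------

    @property
    def n_probes(self) -> int:
        return len(self.probe_ids)

    @property
    def n_profiles(self) -> int:
        return self.ranks.shape[0]

    @property
    def instance_ids(self) -> list[str]:
        return list(self.meta["instance_id"])

    @property
    def probe_index(self) -> Mapping[str, int]:
        return self._probe_index

    def rows_for(self, instance_ids: Iterable[str]) -> np.ndarray:
        try:
            return np.array([self._row_index[i] for i in instance_ids], dtype=np.intp)
        except KeyError as exc:
            raise KeyError(f"unknown instance id {exc.args[0]!r}") from None

    def profile(self, instance_id: str) -> ReferenceProfile:
        row = self._row_index.get(instance_id)
        if row is None:
            raise KeyError(f"unknown instance id {instance_id!r}")
        md = {c: str(self.meta.at[row, c]) for c in META_COLUMNS if c != "instance_id"}
        return ReferenceProfile(
            instance_id=instance_id,
            signed_ranks=self.ranks[row],
            metadata=md,
            probe_index=self._probe_index,
        )

    def profiles(self) -> Iterable[ReferenceProfile]:
        for iid in self.meta["instance_id"]:
            yield self.profile(iid)

    # -- treatment sets --------------------------------------------------

    def group_sets(self, mode: GroupBy) -> dict[TreatmentSetKey, list[str]]:
        """Partition all profiles into treatment sets.

        Every profile belongs to exactly one set; an empty cell-line string
        is a distinct category, never merged with others.
        """
        mode = GroupBy(mode)
        if self.n_profiles == 0:
            raise ValueError("cannot group an empty database")
        sets: dict[TreatmentSetKey, list[str]] = {}
        for iid, pert, cell in zip(
            self.meta["instance_id"], self.meta["perturbagen"], self.meta["cell_line"]
        ):
            if mode is GroupBy.DRUG:
                key = TreatmentSetKey(str(pert))
            else:
                key = TreatmentSetKey(str(pert), str(cell))
            sets.setdefault(key, []).append(iid)
        return dict(sorted(sets.items(), key=lambda kv: kv[0].sort_key))

    def filter_by_compound_list(
        self, approved: Iterable[str], case_fold: bool = False
    ) -> "ReferenceDatabase":
        """Retain only profiles whose perturbagen appears in ``approved``.

        Matching is exact by default; with ``case_fold=True`` both sides are
        case-folded first.
        """
        approved = set(approved)
        if case_fold:
            approved = {a.casefold() for a in approved}
            keep = self.meta["perturbagen"].astype(str).str.casefold().isin(approved)
        else:
            keep = self.meta["perturbagen"].astype(str).isin(approved)
        if not keep.any():
            raise ValueError("no profiles remain after compound filtering")
        return ReferenceDatabase(
            self.probe_ids,
            self.ranks[keep.to_numpy()],
            self.meta.loc[keep].reset_index(drop=True),
        )

    # -- persistence -----------------------------------------------------

    def save(self, path: str | Path) -> None:
        path = Path(path)
        path.mkdir(parents=True, exist_ok=True)
        (path / "probes.txt").write_text("\n".join(self.probe_ids) + "\n")
        with gzip.open(path / "ranks.tsv.gz", "wt") as fh:
            for iid, row in zip(self.meta["instance_id"], self.ranks):
                fh.write(iid + "\t" + "\t".join(str(int(v)) for v in row) + "\n")
        self.meta.loc[:, list(META_COLUMNS)].to_csv(
            path / "instances.tsv", sep="\t", index=False
        )

    @classmethod
    def load(cls, path: str | Path) -> "ReferenceDatabase":
        path = Path(path)
        probe_ids = [
            line for line in (path / "probes.txt").read_text().splitlines() if line
        ]
        meta = pd.read_csv(path / "instances.tsv", sep="\t", dtype=str).fillna("")
        ids: list[str] = []
        rows: list[np.ndarray] = []
        with gzip.open(path / "ranks.tsv.gz", "rt") as fh:
            for line in fh:
                parts = line.rstrip("\n").split("\t")
                ids.append(parts[0])
                rows.append(np.array(parts[1:], dtype=np.int32))
        ranks = np.vstack(rows) if rows else np.empty((0, len(probe_ids)), np.int32)
        if ids != list(meta["instance_id"]):
            raise ValueError("instances.tsv and ranks.tsv.gz disagree on instance ids")
        return cls(probe_ids, ranks, meta)


def build_database(
    instances: Sequence[ExpressionInstance],
    probe_ids: Sequence[str],
    control_aggregate: str = "mean",
) -> ReferenceDatabase:
    """Build a signed-rank database from raw expression instances.

    One profile is produced per non-control instance (differential against
    the same-plate controls, then signed-rank); control instances are
    consumed and not stored.
    """
    probe_ids = list(probe_ids)
    n = len(probe_ids)
    for inst in instances:
        if inst.values.size != n:
            raise ValueError(
                f"instance {inst.instance_id!r} has {inst.values.size} values, "
                f"expected {n} (one per probe)"
            )
    treated = [i for i in instances if not i.is_control]
    if not treated:
        raise ValueError("input contains no non-control instances")
    controls_by_plate: dict[str, list[ExpressionInstance]] = {}
    for inst in instances:
        if inst.is_control:
            controls_by_plate.setdefault(inst.plate_id, []).append(inst)
    orphans = [t.instance_id for t in treated if t.plate_id not in controls_by_plate]
    if orphans:
        raise ValueError(
            f"plates lack control instances for treated instances: {orphans}"
        )
    rank_rows = np.empty((len(treated), n), dtype=np.int32)
    meta_rows = []
    for i, inst in enumerate(treated):
        d = differential_profile(
            inst, controls_by_plate[inst.plate_id], aggregate=control_aggregate
        )
        rank_rows[i] = signed_rank(d)
        meta_rows.append(
            {
                "instance_id": inst.instance_id,
                "perturbagen": inst.perturbagen,
                "cell_line": inst.cell_line,
                "dose": inst.dose,
                "time": inst.time,
                "plate_id": inst.plate_id,
            }
        )
    meta = pd.DataFrame(meta_rows, columns=list(META_COLUMNS))
    log.info("built database: %d profiles x %d probes", len(treated), n)
    return ReferenceDatabase(probe_ids, rank_rows, meta)


def read_expression_dataset(
    expression_tsv: str | Path, metadata_tsv: str | Path
) -> tuple[list[ExpressionInstance], list[str]]:
    """Read the TSV input pair (expression matrix + instance metadata).

    The expression matrix has ``probe_id`` as its first column and one
    column per instance; the metadata table carries the standard columns
    plus ``is_control`` (0/1).
    """
    try:
        expr = pd.read_csv(expression_tsv, sep="\t", index_col=0)
    except Exception as exc:  # pragma: no cover - pandas message passthrough
        raise ValueError(f"malformed expression TSV {expression_tsv}: {exc}") from exc
    bad = expr.index[expr.isna().any(axis=1)]
    if len(bad):
        line = int(np.where(expr.index == bad[0])[0][0]) + 2  # header is line 1
        raise ValueError(
            f"expression TSV {expression_tsv}: missing/non-numeric value for "
            f"probe {bad[0]!r} (line {line})"
        )
    try:
        meta = pd.read_csv(metadata_tsv, sep="\t", dtype=str).fillna("")
    except Exception as exc:  # pragma: no cover
        raise ValueError(f"malformed metadata TSV {metadata_tsv}: {exc}") from exc
    required = {"instance_id", "perturbagen", "cell_line", "plate_id", "is_control"}
    missing = required - set(meta.columns)
    if missing:
        raise ValueError(f"metadata TSV is missing columns {sorted(missing)}")
    probe_ids = [str(p) for p in expr.index]
    instances = []
    for _, row in meta.iterrows():
        iid = str(row["instance_id"])
        if iid not in expr.columns:
            raise ValueError(f"instance {iid!r} has metadata but no expression column")
        instances.append(
            ExpressionInstance(
                instance_id=iid,
                values=expr[iid].to_numpy(dtype=float),
                plate_id=str(row["plate_id"]),
                perturbagen=str(row["perturbagen"]),
                cell_line=str(row["cell_line"]),
                dose=str(row.get("dose", "")),
                time=str(row.get("time", "")),
                is_control=str(row["is_control"]).strip() in ("1", "true", "True"),
            )
        )
    return instances, probe_ids
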