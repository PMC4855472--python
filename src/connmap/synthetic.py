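"""Synthetic perturbation datasets with planted effects and known truth.

The generator emulates the structure of an L1000-style reference
collection at desk scale: plates carrying vehicle-control instances plus
treated instances, a probe universe defaulting to the 978 landmark genes,
and perturbagens observed in one or more instances per cell line.

Each instance's expression vector is noise around a zero baseline, with a
perturbagen's planted effect added to its designated up-probes and
subtracted from its down-probes.  Noise is Gaussian by default; with a
finite ``noise_df`` it is multivariate Student-t: every instance draws a
single scale factor ``sqrt(df / chi2_df)`` shared across probes, so a
heavy-tailed setting produces occasional whole-instance outliers — the
kind of wild replicate that motivates median (rather than mean) set
aggregation.  Because controls are aggregated per plate, finite control
counts also induce realistic within-plate correlation between profiles.

A ``truth.tsv`` table records which perturbagens are planted mimics or
reversers of the companion query signature, so pipeline recovery can be
checked end to end.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd

from .refdb import (
    ExpressionInstance,
    GroupBy,
    ReferenceDatabase,
    TreatmentSetKey,
    build_database,
)
from .scoring import instance_scores_matrix, max_denominator, signature_index_arrays
from .significance import null_set_scores, per_set_rngs
from .signatures import QuerySignature, sample_signature_indices

#: number of directly measured landmark genes in the L1000 assay
N_LANDMARK = 978


def default_probe_ids(n: int) -> list[str]:
    return [f"PR{i:05d}" for i in range(n)]


@dataclass(frozen=True)
class PerturbagenSpec:
    """One perturbagen x cell-line condition and its planted effect."""

    name: str
    cell_line: str
    n_instances: int
    up_probes: tuple[str, ...] = ()
    down_probes: tuple[str, ...] = ()
    effect_size: float = 0.0
    profile_sd: float = 0.0  # strength of the shared characteristic response
    noise_df: float | None = None  # overrides the config-level setting
    role: str = "null"  # mimic | reverser | null, relative to the companion query

    def __post_init__(self) -> None:
        if self.n_instances < 1:
            raise ValueError(f"{self.name}: n_instances must be >= 1")
        if self.role not in ("mimic", "reverser", "null"):
            raise ValueError(f"{self.name}: unknown role {self.role!r}")


@dataclass(frozen=True)
class SimulationConfig:
    n_probes: int
    n_plates: int
    controls_per_plate: int
    perturbagens: tuple[PerturbagenSpec, ...]
    noise_sd: float = 1.0
    noise_df: float = math.inf
    seed: int = 0
    #: seed for the characteristic response profiles; defaults to ``seed``.
    #: Setting it separately keeps the perturbagen identities fixed while
    #: the measurement noise is re-drawn (replicate "reruns").
    profile_seed: int | None = None
    probe_ids: tuple[str, ...] = field(default=())

    def __post_init__(self) -> None:
        if self.n_probes < 1 or self.n_plates < 1 or self.controls_per_plate < 1:
            raise ValueError("n_probes, n_plates, controls_per_plate must be >= 1")
        if not self.perturbagens:
            raise ValueError("config defines no perturbagens")
        probes = self.probe_ids or tuple(default_probe_ids(self.n_probes))
        if len(probes) != self.n_probes:
            raise ValueError("probe_ids length does not match n_probes")
        object.__setattr__(self, "probe_ids", probes)
        universe = set(probes)
        for spec in self.perturbagens:
            stray = (set(spec.up_probes) | set(spec.down_probes)) - universe
            if stray:
                raise ValueError(
                    f"{spec.name}: effect probes not in the universe: {sorted(stray)}"
                )


def _noise(
    rng: np.random.Generator, n: int, sd: float, df: float
) -> np.ndarray:
    """One instance's noise vector; multivariate-t via a shared scale."""
    scale = 1.0 if math.isinf(df) else math.sqrt(df / rng.chisquare(df))
    return sd * scale * rng.standard_normal(n)


def simulate_database(
    cfg: SimulationConfig,
) -> tuple[list[ExpressionInstance], pd.DataFrame]:
    """Generate instances plus the planted-role truth table.

    Deterministic given ``cfg.seed``.  Treated instances fill plates
    sequentially (so small treatment sets stay on one plate, as in real
    plate layouts) and every plate carries ``controls_per_plate`` controls.
    """
    rng = np.random.default_rng(np.random.SeedSequence(cfg.seed))
    probe_index = {p: i for i, p in enumerate(cfg.probe_ids)}
    n_treated = sum(s.n_instances for s in cfg.perturbagens)
    capacity = math.ceil(n_treated / cfg.n_plates)
    plates_used = math.ceil(n_treated / capacity)

    instances: list[ExpressionInstance] = []
    for plate in range(plates_used):
        pid = f"PLATE{plate:03d}"
        for c in range(cfg.controls_per_plate):
            instances.append(
                ExpressionInstance(
                    instance_id=f"{pid}_CTL{c}",
                    values=_noise(rng, cfg.n_probes, cfg.noise_sd, cfg.noise_df),
                    plate_id=pid,
                    perturbagen="DMSO",
                    cell_line="",
                    is_control=True,
                )
            )

    truth_rows = []
    slot = 0
    for pert_i, spec in enumerate(cfg.perturbagens):
        df = cfg.noise_df if spec.noise_df is None else spec.noise_df
        planted = spec.effect_size != 0.0 and (spec.up_probes or spec.down_probes)
        characteristic = None
        if spec.profile_sd != 0.0:
            # the perturbagen's reproducible transcriptome-wide response,
            # shared by its replicate instances; drawn from a stream keyed
            # by (seed, perturbagen) so it is stable across noise settings
            base = cfg.seed if cfg.profile_seed is None else cfg.profile_seed
            prng = np.random.default_rng(np.random.SeedSequence([base, pert_i, 17]))
            characteristic = spec.profile_sd * prng.standard_normal(cfg.n_probes)
        for j in range(spec.n_instances):
            pid = f"PLATE{slot // capacity:03d}"
            values = _noise(rng, cfg.n_probes, cfg.noise_sd, df)
            if characteristic is not None:
                values += characteristic
            if planted:
                up = [probe_index[p] for p in spec.up_probes]
                down = [probe_index[p] for p in spec.down_probes]
                values[up] += spec.effect_size
                values[down] -= spec.effect_size
            instances.append(
                ExpressionInstance(
                    instance_id=f"{spec.name}_{spec.cell_line}_{j:02d}",
                    values=values,
                    plate_id=pid,
                    perturbagen=spec.name,
                    cell_line=spec.cell_line,
                    dose="10uM",
                    time="24h",
                    is_control=False,
                )
            )
            slot += 1
        truth_rows.append(
            {
                "perturbagen": spec.name,
                "cell_line": spec.cell_line,
                "role": spec.role if planted else "null",
            }
        )
    truth = pd.DataFrame(truth_rows, columns=["perturbagen", "cell_line", "role"])
    return instances, truth


def write_dataset(
    instances: Sequence[ExpressionInstance],
    probe_ids: Sequence[str],
    truth: pd.DataFrame,
    out_dir: str | Path,
) -> None:
    """Emit the TSV input pair consumed by database construction + truth."""
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    expr = pd.DataFrame(
        {inst.instance_id: inst.values for inst in instances},
        index=list(probe_ids),
    )
    expr.index.name = "probe_id"
    expr.to_csv(out / "expression.tsv", sep="\t", float_format="%.6f")
    meta = pd.DataFrame(
        [
            {
                "instance_id": i.instance_id,
                "perturbagen": i.perturbagen,
                "cell_line": i.cell_line,
                "dose": i.dose,
                "time": i.time,
                "plate_id": i.plate_id,
                "is_control": int(i.is_control),
            }
            for i in instances
        ]
    )
    meta.to_csv(out / "metadata.tsv", sep="\t", index=False)
    truth.to_csv(out / "truth.tsv", sep="\t", index=False)


# ---------------------------------------------------------------------------
# ready-made study configurations


def planted_study(
    n_probes: int = N_LANDMARK,
    n_mimic: int = 5,
    n_reverser: int = 5,
    n_null: int = 30,
    instances_per_set: int | Sequence[int] = 3,
    m_up: int = 15,
    m_down: int = 15,
    effect_size: float = 5.0,
    noise_sd: float = 1.0,
    noise_df: float = math.inf,
    controls_per_plate: int = 4,
    plate_capacity: int = 30,
    seed: int = 0,
) -> tuple[SimulationConfig, QuerySignature]:
    """A recovery study: mimics embed the query signature, reversers invert it.

    Mimic perturbagens add ``effect_size`` to the query's up-probes and
    subtract it from the down-probes; reversers do the opposite; null
    perturbagens have no effect.  ``effect_size`` is in units of the noise
    standard deviation when ``noise_sd=1``.
    """
    rng = np.random.default_rng(np.random.SeedSequence([seed, 7]))
    probes = tuple(default_probe_ids(n_probes))
    sig_idx = sample_signature_indices(rng, 1, m_up + m_down, n_probes)[0]
    sig = QuerySignature(
        name="planted",
        up=tuple(probes[i] for i in sig_idx[:m_up]),
        down=tuple(probes[i] for i in sig_idx[m_up:]),
    )
    sizes = (
        [instances_per_set] * (n_mimic + n_reverser + n_null)
        if isinstance(instances_per_set, int)
        else list(instances_per_set)
    )
    specs = []
    i = 0
    for k in range(n_mimic):
        specs.append(
            PerturbagenSpec(
                name=f"MIMIC{k:02d}",
                cell_line="CL1",
                n_instances=sizes[i % len(sizes)],
                up_probes=sig.up,
                down_probes=sig.down,
                effect_size=effect_size,
                role="mimic",
            )
        )
        i += 1
    for k in range(n_reverser):
        specs.append(
            PerturbagenSpec(
                name=f"REVER{k:02d}",
                cell_line="CL1",
                n_instances=sizes[i % len(sizes)],
                up_probes=sig.down,
                down_probes=sig.up,
                effect_size=effect_size,
                role="reverser",
            )
        )
        i += 1
    for k in range(n_null):
        specs.append(
            PerturbagenSpec(
                name=f"NULL{k:03d}",
                cell_line="CL1",
                n_instances=sizes[i % len(sizes)],
            )
        )
        i += 1
    n_treated = sum(s.n_instances for s in specs)
    cfg = SimulationConfig(
        n_probes=n_probes,
        n_plates=math.ceil(n_treated / plate_capacity),
        controls_per_plate=controls_per_plate,
        perturbagens=tuple(specs),
        noise_sd=noise_sd,
        noise_df=noise_df,
        seed=seed,
    )
    return cfg, sig


def null_landscape_config(
    n_probes: int = N_LANDMARK,
    set_sizes: Sequence[int] = (3, 4, 5, 6, 8, 10, 12, 15, 20, 30, 40, 50),
    sets_per_size: int = 3,
    controls_per_plate: int = 2,
    plate_capacity: int = 25,
    noise_df: float = math.inf,
    profile_sd: float = 0.0,
    seed: int = 0,
) -> SimulationConfig:
    """Query-null perturbagens spanning the 3-50 set-size range.

    Used to map the within-set score-skewness landscape.  With
    ``profile_sd > 0`` every perturbagen carries a reproducible
    transcriptome-wide characteristic response (direction-random, so still
    null with respect to any query), which makes its replicate instances
    mutually correlated the way real treatment sets are.  The small
    control count per plate mirrors real plates, where the shared control
    baseline couples co-plated profiles.
    """
    specs = []
    k = 0
    for size in set_sizes:
        for _ in range(sets_per_size):
            specs.append(
                PerturbagenSpec(
                    name=f"CPD{k:03d}",
                    cell_line="CL1",
                    n_instances=size,
                    profile_sd=profile_sd,
                )
            )
            k += 1
    n_treated = sum(s.n_instances for s in specs)
    return SimulationConfig(
        n_probes=n_probes,
        n_plates=math.ceil(n_treated / plate_capacity),
        controls_per_plate=controls_per_plate,
        perturbagens=tuple(specs),
        noise_df=noise_df,
        seed=seed,
    )


# ---------------------------------------------------------------------------
# skewness diagnostics


def pearson_skewness(xs: Sequence[float]) -> float:
    """Pearson's moment coefficient of skewness, population moments.

    ``gamma = m3 / m2**1.5`` with ``m2``, ``m3`` the second and third
    central moments (1/n normalization).
    """
    xs = np.asarray(xs, dtype=float)
    if xs.size < 3:
        raise ValueError("skewness needs at least 3 values")
    dev = xs - xs.mean()
    m2 = float(np.mean(dev**2))
    if m2 == 0.0:
        raise ValueError("skewness undefined for zero-variance data")
    m3 = float(np.mean(dev**3))
    return m3 / m2**1.5


@dataclass(frozen=True)
class SkewRecord:
    set_key: TreatmentSetKey
    gamma: float
    set_size: int


def skew_landscape(
    db: ReferenceDatabase,
    mode: GroupBy = GroupBy.DRUG_AND_CELL_LINE,
    m_up: int = 15,
    m_down: int = 15,
    n_random: int = 1,
    seed: int = 0,
    kind: str = "within_set",
) -> list[SkewRecord]:
    """Per-set skewness of connection scores under random signatures.

    Two readings of "the skewness of the scores in a set" are supported:

    ``within_set`` (default)
        For each random signature, the Pearson skewness of the member
        *instance* scores within each set (sets of size >= 3).  This is
        the distribution whose asymmetry argues for median rather than
        mean aggregation of instances into a set score; one record is
        produced per (signature, set) pair.

    ``across_signatures``
        The skewness, over ``n_random`` random signatures, of the
        median-aggregated *set* score.  Being a normalized sum of m
        bounded rank draws (then a median), this distribution is close to
        symmetric for any set; it is the distribution the normal null
        model approximates.
    """
    if kind not in ("within_set", "across_signatures"):
        raise ValueError(f"unknown skew landscape kind {kind!r}")
    sets = db.group_sets(mode)
    m = m_up + m_down
    records: list[SkewRecord] = []
    if kind == "within_set":
        rng = np.random.default_rng(np.random.SeedSequence(seed))
        denom = max_denominator(m, db.n_probes)
        idx = sample_signature_indices(rng, n_random, m, db.n_probes)
        for r in range(n_random):
            scores = instance_scores_matrix(
                db.ranks, idx[r, :m_up], idx[r, m_up:], denom
            )
            for key, members in sets.items():
                if len(members) < 3:
                    continue
                vals = scores[db.rows_for(members)]
                if np.ptp(vals) == 0.0:
                    continue
                records.append(
                    SkewRecord(key, pearson_skewness(vals), len(members))
                )
    else:
        if n_random < 3:
            raise ValueError("across_signatures skew needs n_random >= 3")
        rngs = per_set_rngs(seed, len(sets))
        for rng, (key, members) in zip(rngs, sets.items()):
            scores = null_set_scores(db, members, m_up, m_down, n_random, rng)
            records.append(SkewRecord(key, pearson_skewness(scores), len(members)))
    return records


def gamma_exceedance_fraction(
    records: Sequence[SkewRecord],
    threshold: float = 1.0,
    size_range: tuple[int, int] = (3, 50),
) -> float:
    """Fraction of records in the size range with ``gamma > threshold``."""
    lo, hi = size_range
    inrange = [r for r in records if lo <= r.set_size <= hi]
    if not inrange:
        raise ValueError("no skew records in the requested size range")
    return sum(r.gamma > threshold for r in inrange) / len(inrange)


def aggregation_stability(
    cfg: SimulationConfig,
    sig: QuerySignature,
    mode: GroupBy = GroupBy.DRUG_AND_CELL_LINE,
    n_reruns: int = 20,
    seed: int = 0,
) -> pd.DataFrame:
    """Across-rerun variance of median- vs mean-aggregated set scores.

    Each rerun regenerates the dataset with a fresh noise seed (same
    structure and planted truth) and scores every treatment set with the
    same query signature under both aggregation rules.  Returns one row
    per set with the across-rerun variances ``var_median`` and
    ``var_mean``.
    """
    med: dict[TreatmentSetKey, list[float]] = {}
    avg: dict[TreatmentSetKey, list[float]] = {}
    profile_seed = cfg.seed if cfg.profile_seed is None else cfg.profile_seed
    for r in range(n_reruns):
        inst, _ = simulate_database(
            replace(cfg, seed=int(seed + 10_000 + r), profile_seed=profile_seed)
        )
        db = build_database(inst, cfg.probe_ids)
        up_idx, down_idx = signature_index_arrays(sig, db.probe_index)
        denom = max_denominator(sig.m, db.n_probes)
        for key, members in db.group_sets(mode).items():
            scores = instance_scores_matrix(
                db.ranks[db.rows_for(members)], up_idx, down_idx, denom
            )
            med.setdefault(key, []).append(float(np.median(scores)))
            avg.setdefault(key, []).append(float(np.mean(scores)))
    rows = [
        {
            "set_key": key.label,
            "var_median": float(np.var(med[key], ddof=1)),
            "var_mean": float(np.var(avg[key], ddof=1)),
        }
        for key in med
    ]
    return pd.DataFrame(rows)
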