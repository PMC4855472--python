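"""Query signatures: up/down probe lists and their random counterparts.

A query signature is a pair of unordered probe-id lists — genes observed
up- and down-regulated in the condition of interest.  Every probe carries
a direction ``s(g) = +1`` (up) or ``-1`` (down); the total signature size
``m = |up| + |down|`` enters the connection-score denominator.

Random signatures drive the null model: they are drawn uniformly without
replacement from the database's full probe universe and preserve the
query's up/down split, so the null mirrors the query's sign structure.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, replace
from pathlib import Path
from typing import TYPE_CHECKING, Sequence

import numpy as np

if TYPE_CHECKING:  # pragma: no cover
    from .refdb import ReferenceDatabase

log = logging.getLogger(__name__)


@dataclass(frozen=True)
class QuerySignature:
    name: str
    up: tuple[str, ...]
    down: tuple[str, ...]

    def __post_init__(self) -> None:
        up, down = tuple(self.up), tuple(self.down)
        object.__setattr__(self, "up", up)
        object.__setattr__(self, "down", down)
        if len(set(up)) != len(up) or len(set(down)) != len(down):
            raise ValueError(f"signature {self.name!r}: duplicate probes in a list")
        overlap = set(up) & set(down)
        if overlap:
            raise ValueError(
                f"signature {self.name!r}: probes in both lists: {sorted(overlap)}"
            )
        if not up and not down:
            raise ValueError(f"signature {self.name!r}: both probe lists are empty")

    @property
    def m_up(self) -> int:
        return len(self.up)

    @property
    def m_down(self) -> int:
        return len(self.down)

    @property
    def m(self) -> int:
        return len(self.up) + len(self.down)

    @property
    def probes(self) -> tuple[str, ...]:
        return self.up + self.down

    def sign(self, probe_id: str) -> int:
        if probe_id in self.up:
            return 1
        if probe_id in self.down:
            return -1
        raise KeyError(f"probe {probe_id!r} is not in signature {self.name!r}")

    def flipped(self) -> "QuerySignature":
        """Swap the up and down lists (reverses the sign of every score)."""
        return replace(self, name=f"{self.name}(flipped)", up=self.down, down=self.up)


def _read_probe_list(path: str | Path) -> list[str]:
    lines = [ln.strip() for ln in Path(path).read_text().splitlines()]
    probes, seen = [], set()
    dup = 0
    for ln in lines:
        if not ln:
            continue
        if ln in seen:
            dup += 1
            continue
        seen.add(ln)
        probes.append(ln)
    if dup:
        log.warning("%s: collapsed %d duplicate probe id(s)", path, dup)
    return probes


def load_signature(
    path_up: str | Path, path_down: str | Path, name: str | None = None
) -> QuerySignature:
    """Load a signature from two plain-text files (one probe id per line)."""
    up = _read_probe_list(path_up)
    down = _read_probe_list(path_down)
    if name is None:
        name = Path(path_up).stem
    return QuerySignature(name=name, up=tuple(up), down=tuple(down))


def load_signature_table(path: str | Path, name: str | None = None) -> QuerySignature:
    """Load a signature from a two-column TSV: probe_id, direction in {up,down}."""
    up: list[str] = []
    down: list[str] = []
    for lineno, ln in enumerate(Path(path).read_text().splitlines(), start=1):
        if not ln.strip():
            continue
        parts = ln.split("\t")
        if len(parts) != 2 or parts[1] not in ("up", "down"):
            raise ValueError(
                f"{path}: line {lineno}: expected 'probe_id<TAB>up|down', got {ln!r}"
            )
        (up if parts[1] == "up" else down).append(parts[0].strip())
    if name is None:
        name = Path(path).stem
    return QuerySignature(
        name=name, up=tuple(dict.fromkeys(up)), down=tuple(dict.fromkeys(down))
    )


def reconcile_with_database(
    sig: QuerySignature, db: "ReferenceDatabase"
) -> QuerySignature:
    """Drop signature probes absent from the database probe universe.

    The returned signature's ``m`` reflects retained probes only, which is
    the ``m`` used in the score denominator.
    """
    idx = db.probe_index
    up = tuple(p for p in sig.up if p in idx)
    down = tuple(p for p in sig.down if p in idx)
    dropped = sig.m - len(up) - len(down)
    if dropped == sig.m:
        raise ValueError(
            f"signature {sig.name!r}: none of its {sig.m} probes are in the database"
        )
    if dropped:
        log.warning(
            "signature %r: dropped %d probe(s) absent from the database (m=%d -> %d)",
            sig.name,
            dropped,
            sig.m,
            len(up) + len(down),
        )
        return QuerySignature(name=sig.name, up=up, down=down)
    return sig


def sample_signature_indices(
    rng: np.random.Generator, n: int, m: int, n_probes: int
) -> np.ndarray:
    """Draw ``n`` index sets of ``m`` distinct probes each, uniformly.

    Returns an ``(n, m)`` integer array.  Implemented as a partial argsort
    of uniform keys, which is exactly a uniform draw without replacement
    and vectorizes over ``n``.
    """
    if m > n_probes:
        raise ValueError(f"cannot draw {m} distinct probes from {n_probes}")
    keys = rng.random((n, n_probes))
    part = np.argpartition(keys, m - 1, axis=1)[:, :m]
    # order within the draw by key so the result is a uniform ordered sample
    row = np.arange(n)[:, None]
    order = np.argsort(keys[row, part], axis=1)
    return part[row, order]


def random_signature(
    m_up: int,
    m_down: int,
    probe_universe: Sequence[str],
    rng: np.random.Generator,
    name: str = "random",
) -> QuerySignature:
    """A size-matched random signature over ``probe_universe``.

    Samples ``m_up + m_down`` distinct probes uniformly without
    replacement; the first ``m_up`` become the up list.  Deterministic for
    a given generator state.
    """
    m = m_up + m_down
    if m == 0:
        raise ValueError("m_up + m_down must be positive")
    if m > len(probe_universe):
        raise ValueError(
            f"m_up + m_down = {m} exceeds the probe universe size "
            f"{len(probe_universe)}"
        )
    idx = sample_signature_indices(rng, 1, m, len(probe_universe))[0]
    probes = [probe_universe[i] for i in idx]
    return QuerySignature(
        name=name, up=tuple(probes[:m_up]), down=tuple(probes[m_up:])
    )
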