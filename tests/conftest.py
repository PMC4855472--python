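import numpy as np
import pandas as pd
import pytest

from connmap import ExpressionInstance, QuerySignature, ReferenceDatabase


def make_db(rank_rows, perturbagens=None, cell_lines=None, probe_ids=None):
    """Assemble a ReferenceDatabase directly from signed-rank rows."""
    rank_rows = np.asarray(rank_rows, dtype=np.int32)
    n_prof, n = rank_rows.shape
    if probe_ids is None:
        probe_ids = [f"p{i}" for i in range(n)]
    if perturbagens is None:
        perturbagens = [f"drug{i}" for i in range(n_prof)]
    if cell_lines is None:
        cell_lines = ["CL1"] * n_prof
    meta = pd.DataFrame(
        {
            "instance_id": [f"inst{i}" for i in range(n_prof)],
            "perturbagen": perturbagens,
            "cell_line": cell_lines,
            "dose": ["10uM"] * n_prof,
            "time": ["24h"] * n_prof,
            "plate_id": ["PL0"] * n_prof,
        }
    )
    return ReferenceDatabase(probe_ids, rank_rows, meta)


def random_signed_perm(rng, n):
    """A uniform random signed permutation of 1..n."""
    ranks = rng.permutation(n) + 1
    signs = rng.choice([-1, 1], size=n)
    return (ranks * signs).astype(np.int32)


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


@pytest.fixture
def worked_db():
    """N=10 database with R(p1)=+10, R(p2)=-9, R(p3)=+4 (one profile)."""
    row = [1, 10, -9, 4, 2, -3, 5, -6, 7, 8]
    return make_db([row], perturbagens=["drugA"])


@pytest.fixture
def worked_sig():
    return QuerySignature(name="worked", up=("p1",), down=("p2",))


def plate_instances(n_treated=2, n_controls=2, n_probes=6, plate="PL0", seed=0):
    """Small raw-instance batch on one plate."""
    rng = np.random.default_rng(seed)
    out = []
    for i in range(n_controls):
        out.append(
            ExpressionInstance(
                instance_id=f"{plate}_ctl{i}",
                values=rng.normal(size=n_probes),
                plate_id=plate,
                perturbagen="DMSO",
                cell_line="",
                is_control=True,
            )
        )
    for i in range(n_treated):
        out.append(
            ExpressionInstance(
                instance_id=f"{plate}_trt{i}",
                values=rng.normal(size=n_probes),
                plate_id=plate,
                perturbagen=f"drug{i}",
                cell_line="CL1",
                is_control=False,
            )
        )
    return out
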