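import numpy as np
import pandas as pd
import pytest

from lifelost import LifeTable, Profile


@pytest.fixture(scope="session")
def constant_table() -> LifeTable:
    """Background hazard 0.02 everywhere: every integral has a closed form."""
    return LifeTable.constant(0.02)


@pytest.fixture
def profile50() -> Profile:
    return Profile(50.0, "F", 1, 2013.0)


def make_registry(rows) -> pd.DataFrame:
    """Build a registry frame from (id, cancer, dep, age, dx, exit, event) tuples."""
    return pd.DataFrame(
        [{"id": r[0], "cancer": r[1], "sex": "F", "dep": r[2], "age_dx": r[3],
          "date_dx": r[4], "date_exit": r[5], "event": r[6]} for r in rows]
    )


def constant_hazard_frame(t, d, t0=None, dep=1, age=50.0, date_dx=2010.0):
    """A ready-made period frame (bypassing window logic) for likelihood checks."""
    t = np.atleast_1d(np.asarray(t, dtype=float))
    d = np.broadcast_to(np.asarray(d, dtype=int), t.shape)
    t0 = np.zeros_like(t) if t0 is None else np.broadcast_to(
        np.asarray(t0, dtype=float), t.shape)
    n = len(t)
    return pd.DataFrame({
        "sex": "F", "dep": dep, "age_dx": float(age), "date_dx": float(date_dx),
        "t0": t0, "t": t, "d": d,
    }, index=range(n))
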