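import numpy as np
import pandas as pd
import pytest

from revex.io import CountMatrix, IntensityMatrix, Signature
from revex.profile_builder import DiseaseProfile
from revex.reversal_screen import DrugProfile


@pytest.fixture
def toy_profile() -> DiseaseProfile:
    return DiseaseProfile({"A": 2.0, "B": -1.0, "C": 1.0})


@pytest.fixture
def mirror_drug(toy_profile) -> DrugProfile:
    return DrugProfile("mirror", {g: -v for g, v in toy_profile.entries.items()}, 1)


def random_profile(rng: np.random.Generator, n: int = 50) -> DiseaseProfile:
    mags = rng.uniform(1.0, 4.0, n)
    signs = rng.choice([-1.0, 1.0], n)
    return DiseaseProfile({f"g{i}": float(s * m) for i, (s, m) in enumerate(zip(signs, mags))})


def matrix_from_groups(case: np.ndarray, ctrl: np.ndarray, kind="intensities", prefix="f"):
    """Stack per-group sample blocks (features × samples) into a labeled matrix."""
    n_feat = case.shape[0]
    cols = [f"case_{i}" for i in range(case.shape[1])] + [
        f"ctrl_{i}" for i in range(ctrl.shape[1])
    ]
    values = pd.DataFrame(
        np.hstack([case, ctrl]),
        index=[f"{prefix}{i}" for i in range(n_feat)],
        columns=cols,
    )
    groups = {c: ("case" if c.startswith("case") else "control") for c in cols}
    cls = CountMatrix if kind == "counts" else IntensityMatrix
    return cls(values, groups)


def make_signature(sid: str, lfc: dict, drug: str | None = None, library="lib") -> Signature:
    return Signature(sid, drug or sid, library, dict(lfc))
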