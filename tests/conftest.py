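"""Shared fixtures: tiny hand-traceable layouts and generator shortcuts."""

import numpy as np
import pytest

from spiderens import GeneratorConfig, LabeledDataset, make_imbalanced


@pytest.fixture
def toy_csv(tmp_path):
    """4-sample, 3-gene expression CSV with control/patient labels."""
    path = tmp_path / "toy.csv"
    path.write_text(
        "sample_id,g1,g2,g3,class\n"
        "s1,1.0,2.0,3.0,control\n"
        "s2,4.0,5.0,6.0,patient\n"
        "s3,7.0,8.0,9.0,control\n"
        "s4,10.0,11.0,12.0,patient\n"
    )
    return path


@pytest.fixture
def keel_file(tmp_path):
    """6-sample KEEL .dat fixture: 4 negative, 2 positive."""
    path = tmp_path / "toy.dat"
    path.write_text(
        "@relation toy\n"
        "@attribute f1 real\n"
        "@attribute f2 real\n"
        "@attribute class {negative, positive}\n"
        "@data\n"
        "0.1,0.2,negative\n"
        "0.3,0.4,negative\n"
        "0.5,0.6,negative\n"
        "0.7,0.8,negative\n"
        "0.9,1.0,positive\n"
        "1.1,1.2,positive\n"
    )
    return path


@pytest.fixture
def trace_layout():
    """13-point 2-D layout with hand-traced neighbor structure (k=3).

    Expected tags, derived by hand from the pairwise distances:
    minority a, b, c (tight triangle) -> strong; w, u (near the majority
    cluster, their noisy minority neighbor v removed from the pool) -> weak;
    v (surrounded by majority) -> noisy/excluded; majority Mn (inside the
    minority triangle) -> noisy; all other majority safe. Class counts 7/6,
    so balancing needs exactly one synthetic sample, seeded at w (the first
    weak sample by index).
    """
    coords = np.array([
        [0.0, 0.0],    # 0 a  minority, strong
        [1.0, 0.0],    # 1 b  minority, strong
        [0.5, 0.8],    # 2 c  minority, strong
        [5.0, 0.0],    # 3 w  minority, weak
        [5.4, 0.7],    # 4 u  minority, weak
        [5.8, 0.0],    # 5 v  minority, noisy -> excluded
        [0.8, 0.4],    # 6 Mn majority, noisy
        [0.5, -2.5],   # 7 Ma majority, safe
        [0.5, -3.5],   # 8 Mb majority, safe
        [1.5, -3.0],   # 9 Mc majority, safe
        [6.3, 0.0],    # 10 Mv1 majority, safe
        [6.1, 0.5],    # 11 Mv2 majority, safe
        [6.5, 0.8],    # 12 Mv3 majority, safe
    ])
    labels = np.array([1, 1, 1, 1, 1, 1, 0, 0, 0, 0, 0, 0, 0])
    data = LabeledDataset(
        coords, labels,
        ["x", "y"], [f"p{i}" for i in range(13)],
    )
    expected = {
        "classification": ["safe"] * 5 + ["noisy", "noisy"] + ["safe"] * 6,
        "strength": ["strong", "strong", "strong", "weak", "weak", "excluded",
                     None, None, None, None, None, None, None],
        "n_synthetic": 1,
        "synthetic_parent": "p3",
        "parent_pool_neighbors": [4, 11, 10],  # u, Mv2, Mv1 by distance
    }
    return data, expected


@pytest.fixture
def flip_layout():
    """8-point 1-D layout where dropping a noisy majority neighbor matters.

    Point p (index 0) has unrestricted 3-NN {m1, mX, Mn}: safe. With the
    noisy majority Mn kept in the partition pool p's neighborhood is
    {m1, Mn, M} (weak); with Mn removed it is {m1, M, m2} (strong).
    """
    coords = np.array([
        [0.0],    # 0 p  minority
        [1.0],    # 1 m1 minority
        [-1.2],   # 2 mX minority, noisy
        [2.0],    # 3 m2 minority
        [1.5],    # 4 Mn majority, noisy
        [-1.8],   # 5 M  majority
        [-2.2],   # 6 M2 majority
        [-2.6],   # 7 M3 majority
    ])
    labels = np.array([1, 1, 1, 1, 0, 0, 0, 0])
    return LabeledDataset(coords, labels, ["x"], [f"q{i}" for i in range(8)])


def small_imbalanced(seed: int, **kwargs) -> LabeledDataset:
    defaults = dict(n_majority=40, n_minority=8, n_features=5,
                    n_informative=3, effect=2.0, seed=seed)
    defaults.update(kwargs)
    data, _ = make_imbalanced(GeneratorConfig(**defaults))
    return data
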