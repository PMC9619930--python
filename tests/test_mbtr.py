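import math

import numpy as np
import pytest

from confpot import (
    ConformerRecord,
    KBlockConfig,
    MBTRConfig,
    descriptor_size_report,
    mbtr_encode,
    mbtr_encode_ensemble,
)

from conftest import rigid_transform


def small_config(grid_n=25):
    """Compact config used for unit tests (full default grids are slower)."""
    return MBTRConfig(
        k1=KBlockConfig(sigma=0.1, grid_min=0.0, grid_max=10.0, grid_n=grid_n,
                        geometry_fn="atomic_number"),
        k2=KBlockConfig(sigma=0.05, scale=0.5, grid_min=0.0, grid_max=8.0,
                        grid_n=grid_n, geometry_fn="distance"),
        k3=KBlockConfig(sigma=0.1, scale=0.8, grid_min=0.0, grid_max=math.pi,
                        grid_n=grid_n, geometry_fn="angle_rad"),
    )


def mbtr_literal_oracle(record, config):
    """Literal transcription of the Gaussian-sum definition: explicit loops
    over atom tuples, channels and grid cells.  Deliberately unvectorized and
    independent of the production encoder."""
    layout = config.layout()
    out = np.zeros(config.n_features)
    elems = record.elements
    coords = np.asarray(record.coords, dtype=float)
    n = len(elems)
    z_of = {"H": 1.0, "C": 6.0, "O": 8.0}

    def add(block, channel, k, center, weight):
        span = layout[(k, channel)]
        dx = (block.grid_max - block.grid_min) / (block.grid_n - 1)
        e0 = block.grid_min - dx / 2.0
        for i in range(block.grid_n):
            lo = e0 + i * dx
            hi = lo + dx
            mass = 0.5 * (math.erf((hi - center) / (block.sigma * math.sqrt(2)))
                          - math.erf((lo - center) / (block.sigma * math.sqrt(2))))
            out[span.start + i] += weight * mass / dx

    if config.k1.enabled:
        for i in range(n):
            add(config.k1, (elems[i],), 1, z_of[elems[i]], 1.0)
    if config.k2.enabled:
        for i in range(n):
            for j in range(i + 1, n):
                d = float(np.linalg.norm(coords[i] - coords[j]))
                g = 1.0 / d if config.k2.geometry_fn == "inverse_distance" else d
                channel = tuple(sorted((elems[i], elems[j])))
                add(config.k2, channel, 2, g, math.exp(-config.k2.scale * d))
    if config.k3.enabled:
        for j in range(n):  # angle vertex
            for i in range(n):
                for k in range(i + 1, n):
                    if j in (i, k):
                        continue
                    d_ij = float(np.linalg.norm(coords[i] - coords[j]))
                    d_jk = float(np.linalg.norm(coords[j] - coords[k]))
                    d_ik = float(np.linalg.norm(coords[i] - coords[k]))
                    cosv = (d_ij**2 + d_jk**2 - d_ik**2) / (2 * d_ij * d_jk)
                    cosv = max(-1.0, min(1.0, cosv))
                    g = cosv if config.k3.geometry_fn == "cosine" else math.acos(cosv)
                    a, b = sorted((elems[i], elems[k]))
                    add(config.k3, (a, elems[j], b), 3, g,
                        math.exp(-config.k3.scale * (d_ij + d_jk + d_ik)))
    return out


def test_rigid_invariance(rng, record_factory):
    config = small_config()
    rec = record_factory(n_atoms=6)
    base = mbtr_encode(rec, config)
    for _ in range(10):
        perm = rng.permutation(rec.n_atoms)
        moved = ConformerRecord(
            "m", "0",
            tuple(rec.elements[i] for i in perm),
            rigid_transform(rng, rec.coords)[perm],
        )
        assert np.abs(mbtr_encode(moved, config) - base).max() < 1e-10


def test_h2_peak_position():
    config = small_config(grid_n=81)
    rec = ConformerRecord("m", "0", ("H", "H"),
                          np.array([[0.0, 0, 0], [0.74, 0, 0]]))
    v = mbtr_encode(rec, config)
    span = config.layout()[(2, ("H", "H"))]
    grid = config.k2.grid
    peak = grid[int(np.argmax(v[span]))]
    nearest = grid[int(np.argmin(np.abs(grid - 0.74)))]
    assert peak == pytest.approx(nearest)


def test_single_atom_k1_mass():
    config = small_config(grid_n=60)
    rec = ConformerRecord("m", "0", ("C",), np.zeros((1, 3)))
    v = mbtr_encode(rec, config)
    layout = config.layout()
    # k2/k3 blocks empty for one atom
    for (k, _ch), span in layout.items():
        if k > 1:
            assert np.all(v[span] == 0.0)
    # the (C,) curve is a unit-mass density: sum * grid step ~ 1
    span = layout[(1, ("C",))]
    assert v[span].sum() * config.k1.dx == pytest.approx(1.0, abs=1e-6)


def test_element_outside_set_raises(record_factory):
    config = MBTRConfig(element_set=("C", "H"))
    rec = ConformerRecord("m", "0", ("C", "O"),
                          np.array([[0.0, 0, 0], [1.2, 0, 0]]))
    with pytest.raises(ValueError, match="O"):
        mbtr_encode(rec, config)


def test_monotone_damping_in_s(record_factory):
    """Increasing the k=2 damping factor never increases any feature value."""
    rec = record_factory(n_atoms=7)
    base = dict(sigma=0.05, grid_min=0.0, grid_max=8.0, grid_n=30,
                geometry_fn="distance")
    lo = MBTRConfig(k2=KBlockConfig(scale=0.3, **base),
                    k1=KBlockConfig(enabled=False, sigma=1, grid_max=10),
                    k3=KBlockConfig(enabled=False, sigma=1, grid_max=3.2))
    hi = MBTRConfig(k2=KBlockConfig(scale=1.2, **base),
                    k1=KBlockConfig(enabled=False, sigma=1, grid_max=10),
                    k3=KBlockConfig(enabled=False, sigma=1, grid_max=3.2))
    assert np.all(mbtr_encode(rec, hi) <= mbtr_encode(rec, lo) + 1e-12)


def test_oracle_equivalence(record_factory):
    config = small_config(grid_n=20)
    for _ in range(8):
        rec = record_factory(n_atoms=5)
        mine = mbtr_encode(rec, config)
        ref = mbtr_literal_oracle(rec, config)
        scale = max(np.abs(ref).max(), 1e-12)
        assert np.abs(mine - ref).max() / scale < 1e-8


def test_ensemble_batching(record_factory):
    config = small_config()
    records = [record_factory(conf=str(i)) for i in range(4)]
    mat = mbtr_encode_ensemble(records, config)
    assert mat.features.shape == (4, config.n_features)
    assert mat.keys == [r.key for r in records]
    # empty input keeps the column count
    empty = mbtr_encode_ensemble([], config)
    assert empty.features.shape == (0, config.n_features)
    # duplicated record gives identical rows; permuting rows permutes output
    twice = mbtr_encode_ensemble([records[0], records[0]], config)
    np.testing.assert_array_equal(twice.features[0], twice.features[1])
    perm = mbtr_encode_ensemble(records[::-1], config)
    np.testing.assert_array_equal(perm.features, mat.features[::-1])


def test_determinism(record_factory):
    config = small_config()
    rec = record_factory()
    a = mbtr_encode(rec, config)
    b = mbtr_encode(rec, config)
    assert np.array_equal(a, b)


class TestSizeReport:
    def test_single_element(self):
        cfg = MBTRConfig(element_set=("H",))
        # uniform grid_n=100 across blocks by default in this config
        cfg = MBTRConfig(
            element_set=("H",),
            k1=KBlockConfig(sigma=0.1, grid_max=10, grid_n=100),
            k2=KBlockConfig(sigma=0.1, grid_max=8, grid_n=100, geometry_fn="distance"),
            k3=KBlockConfig(sigma=0.1, grid_max=3.2, grid_n=100),
        )
        report = descriptor_size_report(cfg)
        assert (report["k1"], report["k2"], report["k3"]) == (100, 100, 100)
        assert report["ratio_with_k3"] == pytest.approx(1.5)

    def test_cho_channel_counts(self):
        cfg = MBTRConfig(
            k1=KBlockConfig(sigma=0.1, grid_max=10, grid_n=100),
            k2=KBlockConfig(sigma=0.1, grid_max=8, grid_n=100, geometry_fn="distance"),
            k3=KBlockConfig(sigma=0.1, grid_max=3.2, grid_n=100),
        )
        report = descriptor_size_report(cfg)
        # 3 elements, 6 unordered pairs, 18 canonical vertex-centered triples
        assert (report["k1"], report["k2"], report["k3"]) == (300, 600, 1800)

    def test_disabled_k3_ratio_one(self):
        cfg = MBTRConfig(k3=KBlockConfig(enabled=False, sigma=0.1, grid_max=3.2))
        assert descriptor_size_report(cfg)["ratio_with_k3"] == pytest.approx(1.0)


def test_fingerprint_distinguishes_configs():
    a = MBTRConfig()
    b = MBTRConfig(k2=KBlockConfig(sigma=0.03, scale=0.5, grid_max=8.0,
                                   grid_n=100, geometry_fn="distance"))
    assert a.fingerprint() != b.fingerprint()
    assert a.fingerprint() == MBTRConfig().fingerprint()
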