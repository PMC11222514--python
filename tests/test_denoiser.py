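"""Denoising-network contracts: local frames, vector lifting, scalar message
attention, SE(3)/permutation equivariance and the chirality switch."""

import numpy as np
import pytest

import diffmol as dm
from diffmol.denoiser import (
    GCPDenoiser,
    build_local_frames,
    lift_noisy_vectors,
    scalar_message_attention,
)
from diffmol.molecules import fully_connected_edges
from diffmol.synthetic import random_rotation

REFLECT = np.diag([1.0, 1.0, -1.0])


def _toy_model(seed=0, **kw):
    return GCPDenoiser(dm.DenoiserConfig.toy(**kw), n_feat=6, T=100,
                       rng=np.random.default_rng(seed))


def _rand_state(rng, n=5, d=6, t=50):
    return dm.LatentState(
        zx=dm.project_zero_cog(rng.standard_normal((n, 3))),
        zh=rng.standard_normal((n, d)), t=t)


# ---------------------------------------------------------------------------
# local frames
# ---------------------------------------------------------------------------

def test_frame_hand_computed_example():
    f = build_local_frames(np.array([1.0, 0, 0]), np.array([0, 1.0, 0]))
    assert f.defined_flag
    assert np.allclose(f.a, np.array([1, -1, 0]) / np.sqrt(2))
    assert np.allclose(f.b, [0, 0, 1])
    assert np.allclose(f.c, np.cross(f.a, f.b))
    m = f.as_matrix()
    assert np.abs(m @ m.T - np.eye(3)).max() < 1e-6  # orthonormal triple


def test_frame_rotation_equivariance():
    rng = np.random.default_rng(1)
    xi, xj = rng.standard_normal(3), rng.standard_normal(3)
    R = random_rotation(rng)
    f = build_local_frames(xi, xj)
    fr = build_local_frames(R @ xi, R @ xj)
    assert np.allclose(fr.a, R @ f.a) and np.allclose(fr.b, R @ f.b)
    assert np.allclose(fr.c, R @ f.c)


def test_frame_chirality_sensitivity_under_point_reflection():
    """Improper operations break frame equivariance via the pseudo-vector b.

    The construction always completes a right-handed triple (det +1).  Under
    point reflection of the inputs the naively co-transformed frame (-a, -b,
    -c) would be left-handed (det -1), but the reconstructed frame keeps b
    fixed (cross products are pseudo-vectors) and stays right-handed — the
    two disagree exactly in the handedness-carrying axes, which is what
    makes mirror images distinguishable.
    """
    rng = np.random.default_rng(2)
    xi, xj = rng.standard_normal(3), rng.standard_normal(3)
    f = build_local_frames(xi, xj)
    fm = build_local_frames(-xi, -xj)
    assert np.linalg.det(f.as_matrix()) == pytest.approx(1.0, abs=1e-9)
    naive = -f.as_matrix()  # equivariant transport of all three axes
    assert np.linalg.det(naive) == pytest.approx(-1.0, abs=1e-9)
    assert np.allclose(fm.a, -f.a) and np.allclose(fm.c, -f.c)
    assert np.allclose(fm.b, f.b)  # pseudo-vector: does not invert
    assert np.abs(fm.as_matrix() - naive).max() > 0.5  # frames disagree


@pytest.mark.parametrize("xi,xj", [
    (np.zeros(3), np.zeros(3)),              # coincident
    (np.array([1.0, 0, 0]), np.array([2.0, 0, 0])),  # collinear with origin
])
def test_degenerate_frames_are_zeroed(xi, xj):
    f = build_local_frames(xi, xj)
    assert not f.defined_flag
    assert np.allclose(f.as_matrix(), 0.0)


# ---------------------------------------------------------------------------
# vector lifting
# ---------------------------------------------------------------------------

def test_lift_two_atom_example():
    zx = np.array([[1.0, 0, 0], [-1.0, 0, 0]])
    edges = fully_connected_edges(2)
    node_vec, edge_vec = lift_noisy_vectors(zx, edges)
    assert np.allclose(node_vec[:, 0, :], -zx)  # displacement to the CoG
    # edge (0,1) carries x_1 - x_0 = (-2, 0, 0) and edge (1,0) the opposite
    lookup = {tuple(e): v for e, v in zip(edges, edge_vec[:, 0, :])}
    assert np.allclose(lookup[(0, 1)], [-2, 0, 0])
    assert np.allclose(lookup[(1, 0)], [2, 0, 0])


def test_lift_single_atom_is_zero():
    node_vec, edge_vec = lift_noisy_vectors(np.zeros((1, 3)),
                                            fully_connected_edges(1))
    assert np.allclose(node_vec, 0.0) and edge_vec.shape[0] == 0


def test_lift_rotation_equivariance_including_pseudo():
    rng = np.random.default_rng(3)
    zx = dm.project_zero_cog(rng.standard_normal((4, 3)))
    edges = fully_connected_edges(4)
    R = random_rotation(rng)
    nv, ev = lift_noisy_vectors(zx, edges, with_pseudo=True)
    nvr, evr = lift_noisy_vectors(zx @ R.T, edges, with_pseudo=True)
    assert np.abs(nvr - nv @ R.T).max() < 1e-12
    assert np.abs(evr - ev @ R.T).max() < 1e-12


# ---------------------------------------------------------------------------
# scalar message attention
# ---------------------------------------------------------------------------

def test_sma_gate_properties():
    rng = np.random.default_rng(4)
    msg = rng.standard_normal((6, 8))
    gate = scalar_message_attention(msg, np.zeros(8), 0.0)
    assert np.allclose(gate, 0.5)  # zero logits sit at the logistic midpoint
    gate2 = scalar_message_attention(msg, rng.standard_normal(8), 0.3)
    assert np.all((gate2 > 0) & (gate2 < 1))
    off = scalar_message_attention(msg, rng.standard_normal(8), enabled=False)
    assert np.allclose(off, 1.0)


def test_sma_off_equals_gate_clamped_to_one():
    """A use_sma=False model matches a use_sma=True model whose gate
    saturates at exactly 1 (same weights otherwise)."""
    rng = np.random.default_rng(5)
    z = _rand_state(rng)
    on = _toy_model(seed=7, use_sma=True)
    off = _toy_model(seed=7, use_sma=False)
    for name, p in on.params.items():
        if ".sma." in name:
            # logits >= 37 make the float64 logistic exactly 1.0
            p.data = (np.zeros_like(p.data) if name.endswith(".W")
                      else np.full_like(p.data, 1000.0))
        else:
            off.params[name].data = p.data.copy()
    p_on, p_off = on.predict(z, 50), off.predict(z, 50)
    assert np.array_equal(p_on.eps_x, p_off.eps_x)
    assert np.array_equal(p_on.eps_h, p_off.eps_h)


# ---------------------------------------------------------------------------
# full network contracts
# ---------------------------------------------------------------------------

def test_denoiser_se3_equivariance():
    """Rotation + translation of the input rotates eps_x, fixes eps_h.

    Translations never reach the network (coordinates are centred), so the
    probe translates before projection.
    """
    rng = np.random.default_rng(6)
    model = _toy_model(seed=1)
    raw = rng.standard_normal((6, 3))
    zh = rng.standard_normal((6, 6))
    R = random_rotation(rng)
    u = rng.normal(0, 5, (1, 3))
    z = dm.LatentState(zx=dm.project_zero_cog(raw), zh=zh, t=40)
    zt = dm.LatentState(zx=dm.project_zero_cog(raw @ R.T + u), zh=zh, t=40)
    p, pt = model.predict(z, 40), model.predict(zt, 40)
    assert np.abs(pt.eps_x - p.eps_x @ R.T).max() < 1e-4
    assert np.abs(pt.eps_h - p.eps_h).max() < 1e-4


def test_denoiser_permutation_equivariance():
    rng = np.random.default_rng(7)
    model = _toy_model(seed=2)
    z = _rand_state(rng)
    perm = rng.permutation(z.N)
    zp = dm.LatentState(zx=z.zx[perm], zh=z.zh[perm], t=z.t)
    p, pp = model.predict(z, z.t), model.predict(zp, z.t)
    assert np.abs(pp.eps_x - p.eps_x[perm]).max() < 1e-10
    assert np.abs(pp.eps_h - p.eps_h[perm]).max() < 1e-10


@pytest.mark.parametrize("seed", range(12))
def test_reflection_sensitivity_iff_frames(seed):
    """With frames on, mirroring generic inputs changes the scalar outputs
    (> 1e-3 over a handful of probes); with frames off the outputs are
    exactly reflection-equivariant."""
    rng = np.random.default_rng(seed)
    on = _toy_model(seed=seed, use_frames=True)
    off = _toy_model(seed=seed, use_frames=False)
    best = 0.0
    for _ in range(5):
        z = _rand_state(rng, n=6)
        zm = dm.LatentState(zx=z.zx @ REFLECT, zh=z.zh, t=z.t)
        p, pm = on.predict(z, z.t), on.predict(zm, z.t)
        best = max(best, np.abs(pm.eps_h - p.eps_h).max())
        q, qm = off.predict(z, z.t), off.predict(zm, z.t)
        assert np.abs(qm.eps_h - q.eps_h).max() < 1e-10
        assert np.abs(qm.eps_x - q.eps_x @ REFLECT).max() < 1e-10
    assert best > 1e-3


def test_denoiser_single_atom_predicts_zero_coordinate_noise():
    model = _toy_model(seed=3)
    z = dm.LatentState(zx=np.zeros((1, 3)),
                       zh=np.random.default_rng(8).standard_normal((1, 6)),
                       t=10)
    p = model.predict(z, 10)
    assert np.allclose(p.eps_x, 0.0)
    assert p.eps_h.shape == (1, 6)


def test_denoiser_output_always_zero_cog():
    rng = np.random.default_rng(9)
    model = _toy_model(seed=4)
    for n in (2, 3, 7):
        z = _rand_state(rng, n=n)
        p = model.predict(z, z.t)
        assert np.abs(p.eps_x.mean(axis=0)).max() < 1e-6


def test_conditioning_requirements_enforced():
    rng = np.random.default_rng(10)
    z = _rand_state(rng)
    cond_model = _toy_model(seed=5, condition_dim=1)
    with pytest.raises(ValueError):
        cond_model.predict(z, 10)  # missing condition value
    uncond = _toy_model(seed=5)
    with pytest.raises(ValueError):
        uncond.predict(z, 10, cond=1.0)  # unexpected condition value


def test_frames_toggle_changes_parameter_count():
    with_frames = _toy_model(seed=6, use_frames=True)
    without = _toy_model(seed=6, use_frames=False)
    assert with_frames.n_parameters() > without.n_parameters()


def test_checkpoint_round_trip(tmp_path):
    rng = np.random.default_rng(11)
    model = _toy_model(seed=12)
    z = _rand_state(rng)
    path = tmp_path / "model.json"
    model.save(path)
    clone = GCPDenoiser.load(path)
    p, pc = model.predict(z, 30), clone.predict(z, 30)
    assert np.array_equal(p.eps_x, pc.eps_x)
    assert np.array_equal(p.eps_h, pc.eps_h)
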