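"""Neutrosophic conversion, neighborhood statistics and the gated loss."""

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from neutrofill import (
    LossConfig,
    NeighborhoodStats,
    NeutrosophicTriple,
    PixelDomain,
    image_loss,
    neighborhood_mean_triple,
    neighborhood_values,
    neutrosophic_table,
    pixel_loss,
    to_neutrosophic,
)
from neutrofill.errors import (
    ConfigurationError,
    DomainError,
    PreconditionError,
    ShapeError,
)

D255 = PixelDomain(255)


# ---------------------------------------------------------------------------
# independent brute-force oracle (double loop over pixels and neighborhoods)
# ---------------------------------------------------------------------------


def brute_force_image_loss(gen, real, mask, config, domain):
    """Naive reference: per-pixel loops through the public scalar operations."""
    gen, real = np.asarray(gen, float), np.asarray(real, float)
    h, w = gen.shape
    total, gated, evaluated = 0.0, 0, 0
    weights = None
    for r in range(h):
        for c in range(w):
            if config.scope == "masked_only" and not mask[r, c]:
                continue
            evaluated += 1
            gv = neighborhood_values(gen, r, c, config.border_policy)
            rv = neighborhood_values(real, r, c, config.border_policy)
            if config.weight_kernel is not None:
                weights = list(config.weight_kernel)
            gs = neighborhood_mean_triple(gv, domain, weights)
            rs = neighborhood_mean_triple(rv, domain, weights)
            d = gs.mean_triple.as_array() - rs.mean_triple.as_array()
            if np.all(np.abs(d) < config.threshold):
                gated += 1
                continue
            if config.aggregation == "mean_triple_sq":
                total += float(d @ d)
            else:
                for a, b in zip(gv, rv):
                    da = to_neutrosophic(a, domain).as_array() - to_neutrosophic(
                        b, domain
                    ).as_array()
                    total += float(da @ da)
    return total, gated, evaluated


# ---------------------------------------------------------------------------
# pixel -> triple conversion
# ---------------------------------------------------------------------------


@pytest.mark.parametrize(
    "value,max_value,expected",
    [
        (0, 255, (1.0, 0.0, 0.0)),
        (255, 255, (0.0, 0.0, 1.0)),
        (1, 255, (1 - 1 / 255, (1 / 255) * (1 - 1 / 255), 1 / 255)),
        (2, 4, (0.5, 0.25, 0.5)),
    ],
)
def test_to_neutrosophic_examples(value, max_value, expected):
    t = to_neutrosophic(value, PixelDomain(max_value))
    assert (t.T, t.I, t.F) == pytest.approx(expected, abs=1e-15)


def test_to_neutrosophic_printed_precision():
    """Intensity 1 rounds to the conventional 3-4 digit presentation."""
    t = to_neutrosophic(1, D255)
    assert round(t.T, 3) == 0.996
    assert round(t.I, 4) == 0.0039
    assert round(t.F, 4) == 0.0039


def test_to_neutrosophic_errors():
    with pytest.raises(DomainError, match="-1"):
        to_neutrosophic(-1, D255)
    with pytest.raises(DomainError, match="256"):
        to_neutrosophic(256, D255)
    with pytest.raises(ConfigurationError):
        PixelDomain(0)


def test_table_identities_and_endpoints():
    """T + F = 1 and I = T*F exactly for every intensity of the 8-bit table."""
    table = neutrosophic_table(D255)
    assert len(table) == 256
    assert (table[0].T, table[0].I, table[0].F) == (1.0, 0.0, 0.0)
    assert (table[255].T, table[255].I, table[255].F) == (0.0, 0.0, 1.0)
    for t in table:
        assert t.T + t.F == 1.0
        assert t.I == t.T * t.F
        assert 0.0 <= t.I <= 0.25


def test_table_monotonicity():
    table = neutrosophic_table(D255)
    ts = np.array([t.T for t in table])
    fs = np.array([t.F for t in table])
    is_ = np.array([t.I for t in table])
    assert (np.diff(ts) < 0).all()
    assert (np.diff(fs) > 0).all()
    assert (np.diff(is_[:128]) > 0).all()  # increasing up to mid-intensity
    assert (np.diff(is_[128:]) < 0).all()  # decreasing beyond
    assert is_.argmax() in (127, 128)  # extremum at mid-intensity


def test_table_small_domains():
    binary = neutrosophic_table(PixelDomain(1))
    assert [(t.T, t.I, t.F) for t in binary] == [(1, 0, 0), (0, 0, 1)]
    t2 = neutrosophic_table(PixelDomain(4))[2]
    assert (t2.T, t2.I, t2.F) == (0.5, 0.25, 0.5)


# ---------------------------------------------------------------------------
# neighborhoods
# ---------------------------------------------------------------------------

IMG3 = np.arange(9.0).reshape(3, 3)  # [[0,1,2],[3,4,5],[6,7,8]]


def test_neighborhood_center_valid():
    assert neighborhood_values(IMG3, 1, 1, "valid") == [0, 1, 2, 3, 5, 6, 7, 8]


def test_neighborhood_corner_valid():
    assert neighborhood_values(IMG3, 0, 0, "valid") == [1, 3, 4]


def test_neighborhood_corner_clamp():
    # hand-enumerated clamped coordinates for (0,0)
    assert neighborhood_values(IMG3, 0, 0, "clamp") == [0, 0, 1, 0, 1, 3, 3, 4]


def test_neighborhood_corner_reflect():
    # mirror without edge repeat: -1 -> 1
    assert neighborhood_values(IMG3, 0, 0, "reflect") == [4, 3, 4, 1, 1, 4, 3, 4]


def test_neighborhood_out_of_bounds():
    with pytest.raises(IndexError):
        neighborhood_values(IMG3, 3, 0)


def test_mean_triple_examples():
    zeros = neighborhood_mean_triple([0] * 5, D255)
    assert zeros.mean_triple == NeutrosophicTriple(1.0, 0.0, 0.0)
    assert zeros.n_members == 5
    mixed = neighborhood_mean_triple([0, 255], D255)
    assert mixed.mean_triple.as_array() == pytest.approx([0.5, 0.0, 0.5])
    const = neighborhood_mean_triple([42] * 8, D255)
    assert const.mean_triple.as_array() == pytest.approx(
        to_neutrosophic(42, D255).as_array()
    )


def test_mean_triple_errors():
    with pytest.raises(PreconditionError):
        neighborhood_mean_triple([], D255)
    with pytest.raises(ConfigurationError):
        neighborhood_mean_triple([1, 2], D255, weights=[1.0])


def test_mean_triple_mean_identity_does_not_transfer():
    """T+F=1 survives averaging but I=T*F generally does not."""
    stats = neighborhood_mean_triple([0, 255], D255)
    m = stats.mean_triple
    assert m.T + m.F == pytest.approx(1.0)
    assert m.I != pytest.approx(m.T * m.F)


# ---------------------------------------------------------------------------
# pixel loss
# ---------------------------------------------------------------------------


def _stats(t, i, f, n=8):
    return NeighborhoodStats(NeutrosophicTriple(t, i, f), n)


def test_pixel_loss_examples():
    a = _stats(0.5, 0.1, 0.5)
    assert pixel_loss(a, a, 0.01) == 0.0
    assert pixel_loss(_stats(0.6, 0.1, 0.6), _stats(0.5, 0.1, 0.5), 0.01) == (
        pytest.approx(0.02)
    )
    gated = pixel_loss(
        _stats(0.505, 0.105, 0.505), _stats(0.5, 0.1, 0.5), 0.01
    )
    assert gated == 0.0


def test_pixel_loss_gate_requires_all_components():
    # one component at/over the threshold defeats the gate
    loss = pixel_loss(_stats(0.51, 0.1, 0.49), _stats(0.5, 0.1, 0.5), 0.01)
    assert loss == pytest.approx(0.01**2 * 2)


def test_pixel_loss_negative_threshold():
    with pytest.raises(ConfigurationError):
        pixel_loss(_stats(0.5, 0.1, 0.5), _stats(0.5, 0.1, 0.5), -0.1)


# ---------------------------------------------------------------------------
# image loss
# ---------------------------------------------------------------------------


def test_image_loss_identical_images(rng):
    x = rng.integers(0, 256, size=(6, 6)).astype(float)
    rep = image_loss(x, x)
    assert rep.total == 0.0
    assert rep.gated_count == rep.evaluated_count == 36
    assert (rep.per_pixel == 0).all()


def test_image_loss_full_gating(rng):
    x = rng.integers(0, 256, size=(5, 5)).astype(float)
    y = rng.integers(0, 256, size=(5, 5)).astype(float)
    rep = image_loss(x, y, config=LossConfig(threshold=3.0))
    assert rep.total == 0.0
    assert rep.gated_count == 25


def test_image_loss_shape_and_domain_errors():
    with pytest.raises(ShapeError):
        image_loss(np.zeros((3, 3)), np.zeros((4, 4)))
    with pytest.raises(ShapeError):
        image_loss(np.zeros((3, 3)), np.zeros((3, 3)), mask=np.zeros((2, 2)))
    with pytest.raises(DomainError):
        image_loss(np.full((3, 3), 300.0), np.zeros((3, 3)))


@pytest.mark.parametrize("policy", ["valid", "reflect", "clamp"])
@pytest.mark.parametrize("aggregation", ["mean_triple_sq", "per_element_sq"])
def test_image_loss_matches_brute_force(rng, policy, aggregation):
    """Vectorized loss equals the naive double-loop reference at theta=0."""
    for shape in [(3, 3), (4, 6), (6, 6)]:
        gen = rng.integers(0, 256, size=shape).astype(float)
        real = rng.integers(0, 256, size=shape).astype(float)
        cfg = LossConfig(threshold=0.0, border_policy=policy,
                         aggregation=aggregation)
        rep = image_loss(gen, real, config=cfg)
        total, gated, evaluated = brute_force_image_loss(gen, real, None, cfg, D255)
        assert rep.total == pytest.approx(total, abs=1e-9)
        assert rep.gated_count == gated
        assert rep.evaluated_count == evaluated


def test_image_loss_masked_scope_matches_brute_force(rng):
    gen = rng.integers(0, 256, size=(5, 5)).astype(float)
    real = rng.integers(0, 256, size=(5, 5)).astype(float)
    mask = rng.integers(0, 2, size=(5, 5))
    cfg = LossConfig(threshold=0.005, scope="masked_only")
    rep = image_loss(gen, real, mask=mask, config=cfg)
    total, gated, evaluated = brute_force_image_loss(gen, real, mask, cfg, D255)
    assert rep.total == pytest.approx(total, abs=1e-9)
    assert (rep.gated_count, rep.evaluated_count) == (gated, evaluated)
    assert rep.evaluated_count == int(mask.sum())


def test_image_loss_weighted_matches_brute_force(rng):
    w = np.array([1, 2, 1, 2, 2, 1, 2, 1], dtype=float)
    cfg = LossConfig(threshold=0.0, border_policy="clamp",
                     weight_kernel=tuple(w / w.sum()))
    gen = rng.integers(0, 256, size=(4, 4)).astype(float)
    real = rng.integers(0, 256, size=(4, 4)).astype(float)
    rep = image_loss(gen, real, config=cfg)
    total, _, _ = brute_force_image_loss(gen, real, None, cfg, D255)
    assert rep.total == pytest.approx(total, abs=1e-9)


def test_weight_kernel_validation():
    with pytest.raises(ConfigurationError):
        LossConfig(weight_kernel=(0.5, 0.5))  # wrong length
    with pytest.raises(ConfigurationError):
        LossConfig(weight_kernel=(0.3,) * 8)  # does not sum to 1


@settings(max_examples=25, derandomize=True, deadline=None)
@given(st.integers(0, 2**31 - 1), st.floats(0.0, 0.05))
def test_image_loss_symmetry_and_invariants(seed, theta):
    """Symmetry in the image pair, per-pixel bookkeeping and self-loss zero."""
    r = np.random.default_rng(seed)
    a = r.integers(0, 256, size=(5, 5)).astype(float)
    b = r.integers(0, 256, size=(5, 5)).astype(float)
    cfg = LossConfig(threshold=theta)
    ra, rb = image_loss(a, b, config=cfg), image_loss(b, a, config=cfg)
    assert ra.total == pytest.approx(rb.total, abs=1e-12)
    assert ra.gated_count == rb.gated_count
    assert ra.total == pytest.approx(float(ra.per_pixel.sum()), abs=1e-9)
    assert ra.gated_count + int((ra.per_pixel > 0).sum()) <= ra.evaluated_count
    assert image_loss(a, a, config=cfg).total == 0.0


@settings(max_examples=25, derandomize=True, deadline=None)
@given(st.integers(0, 2**31 - 1), st.floats(0.0, 0.1), st.floats(0.0, 0.1))
def test_image_loss_monotone_gating(seed, t1, t2):
    """A larger threshold gates more pixels and never increases the total."""
    lo, hi = sorted((t1, t2))
    r = np.random.default_rng(seed)
    a = r.integers(0, 256, size=(6, 6)).astype(float)
    b = r.integers(0, 256, size=(6, 6)).astype(float)
    rlo = image_loss(a, b, config=LossConfig(threshold=lo))
    rhi = image_loss(a, b, config=LossConfig(threshold=hi))
    assert rlo.total >= rhi.total - 1e-12
    assert rlo.gated_count <= rhi.gated_count
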