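"""Plot-data resolution and static/interactive rendering."""

import re

import numpy as np
import pytest

from trumpetplot.harmonize import OrientationMode, harmonize_table
from trumpetplot.plotting import TrumpetPlotSpec, build_plot_data, render_interactive, render_static
from trumpetplot.power import PowerCurveSpec
from trumpetplot.synthetic import SimConfig, simulate_sumstats

from conftest import make_record, make_table


def signed_spec(**kw):
    base = dict(orientation=OrientationMode.MINOR_ALLELE_SIGNED)
    base.update(kw)
    return TrumpetPlotSpec(**base)


def four_record_table():
    betas = [0.01, 0.05, 0.1, -0.2]
    return make_table(
        [
            make_record(variant_id=f"rs{i}", pos_bp=100 * (i + 1), eaf=0.2,
                        beta=b)
            for i, b in enumerate(betas)
        ]
    )


def test_min_effect_display_threshold_is_inclusive():
    # |beta| strictly below 0.05 is dropped; exactly 0.05 is kept
    data = build_plot_data(four_record_table(), signed_spec(min_effect_display=0.05))
    assert len(data.points) == 3
    assert data.n_dropped == 1
    assert "rs0" not in set(data.points["variant_id"])


def test_no_filter_keeps_every_record():
    data = build_plot_data(four_record_table(), signed_spec())
    assert len(data.points) == data.n_input == 4
    assert data.n_dropped == 0


def test_filter_accounting_adds_up():
    data = build_plot_data(four_record_table(), signed_spec(min_effect_display=0.11))
    assert len(data.points) + data.n_dropped == data.n_input


def test_equal_effects_get_midpoint_size():
    table = make_table(
        [make_record(variant_id=f"rs{i}", pos_bp=i + 1, beta=0.1) for i in range(3)]
    )
    spec = signed_spec(size_min=10, size_max=90)
    data = build_plot_data(table, spec)
    assert np.all(data.points["size"] == 50.0)


def test_orientation_mismatch_is_fatal_with_count():
    table = make_table(
        [
            make_record(variant_id="a", pos_bp=1, eaf=0.7),
            make_record(variant_id="b", pos_bp=2, eaf=0.8),
            make_record(variant_id="c", pos_bp=3, eaf=0.2),
        ]
    )
    with pytest.raises(ValueError, match="2 records"):
        build_plot_data(table, signed_spec())
    with pytest.raises(ValueError, match="beta < 0"):
        build_plot_data(
            make_table([make_record(variant_id="a", pos_bp=1, beta=-0.1)]),
            TrumpetPlotSpec(orientation=OrientationMode.POSITIVE_EFFECT),
        )


def test_rare_points_clipped_to_axis_not_dropped():
    table = make_table(
        [
            make_record(variant_id="a", pos_bp=1, eaf=1e-7),
            make_record(variant_id="b", pos_bp=2, eaf=0.2),
        ]
    )
    data = build_plot_data(table, signed_spec(f_min=1e-5))
    assert len(data.points) == 2
    assert data.n_clipped == 1
    assert data.points["x"].min() == pytest.approx(1e-5)


def test_x_order_matches_frequency_order(rng):
    eafs = rng.uniform(1e-4, 0.5, size=30)
    table = make_table(
        [make_record(variant_id=f"rs{i}", pos_bp=i + 1, eaf=float(f))
         for i, f in enumerate(eafs)]
    )
    data = build_plot_data(table, signed_spec())
    pts = data.points.sort_values("variant_id", key=lambda s: s.str[2:].astype(int))
    assert np.array_equal(np.argsort(pts["x"]), np.argsort(eafs))


def test_replot_after_double_harmonization_identical():
    table, _ = simulate_sumstats(SimConfig(seed=2, m_common=300, m_rare=30))
    once = harmonize_table(table, OrientationMode.MINOR_ALLELE_SIGNED)
    twice = harmonize_table(once, OrientationMode.MINOR_ALLELE_SIGNED)
    d1 = build_plot_data(once, signed_spec())
    d2 = build_plot_data(twice, signed_spec())
    assert d1.points.equals(d2.points)


@pytest.fixture(scope="module")
def sim_plot_data():
    table, _ = simulate_sumstats(
        SimConfig(seed=4, n_gwas=351_550, m_common=900, m_rare=100)
    )
    signed = harmonize_table(table, OrientationMode.MINOR_ALLELE_SIGNED)
    spec = signed_spec(power=PowerCurveSpec(n=351_550))
    return build_plot_data(signed, spec)


def test_static_svg_has_curves_and_signed_axis(tmp_path, sim_plot_data):
    out = tmp_path / "trumpet.svg"
    render_static(sim_plot_data, out)
    svg = out.read_text()
    assert svg.count("<path") >= 2 * len(sim_plot_data.curves)  # mirrored pairs
    assert "power 0.5" in svg and "power 0.9" in svg
    ys = sim_plot_data.points["y"]
    assert ys.min() < 0 < ys.max()  # two-sided trumpet


def test_higher_level_curve_strictly_outside(sim_plot_data):
    by_level = {c.level: c for c in sim_plot_data.curves}
    assert np.all(by_level[0.9].beta_min > by_level[0.5].beta_min)
    assert all(c.mirrored for c in sim_plot_data.curves)


def test_interactive_hover_payload_matches_spec(tmp_path):
    table = four_record_table()
    spec = signed_spec(hover_fields=("variant_id", "beta", "pvalue"))
    data = build_plot_data(table, spec)
    out = tmp_path / "t.html"
    render_interactive(data, out)
    html = out.read_text()
    circles = re.findall(r"<circle class='pt'[^>]*>", html)
    assert len(circles) == 4
    for c in circles:
        assert "data-variant_id=" in c and "data-beta=" in c and "data-pvalue=" in c
        assert "data-gene=" not in c
    assert len(re.findall(r"<circle[^>]*><title>", html)) == 4


def test_interactive_render_is_deterministic(tmp_path, sim_plot_data):
    p1, p2 = tmp_path / "a.html", tmp_path / "b.html"
    render_interactive(sim_plot_data, p1)
    render_interactive(sim_plot_data, p2)
    assert p1.read_bytes() == p2.read_bytes()


def test_static_render_is_deterministic(tmp_path, sim_plot_data):
    p1, p2 = tmp_path / "a.svg", tmp_path / "b.svg"
    render_static(sim_plot_data, p1)
    render_static(sim_plot_data, p2)
    assert p1.read_bytes() == p2.read_bytes()


def test_interactive_default_filter_reduces_points(tmp_path):
    table, _ = simulate_sumstats(SimConfig(seed=4, m_common=500, m_rare=50))
    signed = harmonize_table(table, OrientationMode.MINOR_ALLELE_SIGNED)
    dense = build_plot_data(signed, signed_spec(min_effect_display=0.0))
    sparse = build_plot_data(signed, signed_spec(min_effect_display=0.05))
    assert len(sparse.points) <= len(dense.points)


def test_empty_points_fatal(tmp_path):
    data = build_plot_data(four_record_table(), signed_spec(min_effect_display=10.0))
    with pytest.raises(ValueError):
        render_static(data, tmp_path / "x.svg")
    with pytest.raises(ValueError):
        render_interactive(data, tmp_path / "x.html")


def test_spec_validation():
    with pytest.raises(ValueError):
        TrumpetPlotSpec(f_min=0.0)
    with pytest.raises(ValueError):
        TrumpetPlotSpec(min_effect_display=-1)
    with pytest.raises(ValueError):
        TrumpetPlotSpec(hover_fields=("variant_id", "bogus"))
    # positive-effect default axis spans toward 1
    spec = TrumpetPlotSpec(orientation=OrientationMode.POSITIVE_EFFECT)
    assert spec.f_max == pytest.approx(1 - 1e-5)
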