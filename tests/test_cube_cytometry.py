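"""Per-cube parameters: distance fields against a brute-force oracle,
geometry/intensity/texture/correlation statistics on constructed inputs,
custom parameters and gating."""

import numpy as np
import pandas as pd
import pytest

from cubecyte import (
    BinaryBiovolume,
    ConfigurationError,
    Gate,
    IntensityStack,
    RangePredicate,
    VoxelGeometry,
    add_custom_parameter,
    assign_voxels,
    build_cube_grid,
    compute_distance_fields,
    gate,
    quantify_all,
    quantify_correlations,
    quantify_geometry,
    quantify_intensity,
    quantify_neighborhood,
    quantify_texture,
)
from cubecyte.cube_cytometry import ParamExpression, ParseError, cube_glcm, _glcm_stats
from cubecyte.synthgen import SynthSpec, make_colony


def brute_force_surface_distance(mask, geometry, substrate_mode):
    """O(n²) oracle: for each foreground voxel, the minimum physical distance
    to any background voxel, including the one-voxel background pad on all
    faces except (in attached mode) below z=0."""
    m = np.pad(mask, 1, constant_values=False)
    if substrate_mode == "attached":
        m[0, 1:-1, 1:-1] = mask[0]
    dz, dy, dx = geometry.spacing_zyx
    fg = np.argwhere(m)
    bg = np.argwhere(~m)
    scale = np.array([dz, dy, dx])
    out = np.full(m.shape, np.inf)
    for v in fg:
        d = np.sqrt((((bg - v) * scale) ** 2).sum(axis=1)).min()
        out[tuple(v)] = d
    return out[1:-1, 1:-1, 1:-1]


class TestDistanceFields:
    def test_slab_on_substratum_attached(self, iso1):
        m = np.zeros((4, 6, 6), bool)
        m[0] = True  # 1-voxel slab at z=0
        fields = compute_distance_fields(BinaryBiovolume(m, iso1), "attached")
        # base is substratum, lateral faces are padded background at d=1,
        # and the voxels above are background at d=1: every voxel d=1
        np.testing.assert_allclose(fields.d_surface[m], 1.0)

    def test_isolated_voxel_floating(self, iso1):
        m = np.zeros((5, 5, 5), bool)
        m[2, 2, 2] = True
        fields = compute_distance_fields(BinaryBiovolume(m, iso1), "floating")
        assert fields.d_surface[2, 2, 2] == pytest.approx(1.0)

    @pytest.mark.parametrize("substrate_mode", ["attached", "floating"])
    @pytest.mark.parametrize("seed", range(3))
    def test_matches_brute_force_oracle(self, substrate_mode, seed):
        rng = np.random.default_rng(seed)
        g = VoxelGeometry(1.0, 1.0, 2.0)  # anisotropic on purpose
        m = rng.random((6, 12, 12)) < 0.5
        m[0, 0, 0] = True  # guarantee nonempty
        fields = compute_distance_fields(BinaryBiovolume(m, g), substrate_mode)
        oracle = brute_force_surface_distance(m, g, substrate_mode)
        np.testing.assert_allclose(fields.d_surface[m], oracle[m], atol=1e-9)

    def test_monotone_under_erosion(self, hemisphere):
        from scipy import ndimage

        fields = compute_distance_fields(hemisphere, "attached")
        eroded = BinaryBiovolume(
            ndimage.binary_erosion(hemisphere.mask), hemisphere.geometry
        )
        fields_e = compute_distance_fields(eroded, "attached")
        sel = eroded.mask
        assert np.all(fields_e.d_surface[sel] <= fields.d_surface[sel] + 1e-9)

    def test_com_inside_bounding_box(self, hemisphere):
        fields = compute_distance_fields(hemisphere)
        nz, ny, nx = hemisphere.shape
        g = hemisphere.geometry
        assert 0 <= fields.com[0] <= nz * g.dz
        assert 0 <= fields.com[1] <= ny * g.dy
        assert 0 <= fields.com[2] <= nx * g.dx
        assert fields.com_projected[0] == 0.0


class TestGeometryParameters:
    def _solid_block(self, iso1, shape=(8, 24, 24), edge=4.0):
        mask = BinaryBiovolume(np.ones(shape, bool), iso1)
        grid = build_cube_grid(mask, edge)
        table = assign_voxels(mask, grid)
        fields = compute_distance_fields(mask, "attached")
        quantify_geometry(table, mask, fields)
        return table, mask

    def test_interior_cube_full_and_sealed(self, iso1):
        table, _ = self._solid_block(iso1)
        interior = table.df[
            (table.df["i"] == 2) & (table.df["j"] == 2) & (table.df["k"] == 0)
        ]
        assert interior["fill_fraction"].iloc[0] == 1.0
        # in attached mode the bottom face of a k=0 cube is substratum and
        # the cube is surrounded laterally: only top-face exposure is absent
        # too (k=1 cube above is foreground)
        assert interior["exposed_surface_area_um2"].iloc[0] == 0.0

    def test_half_filled_cube(self, iso1):
        m = np.zeros((8, 8, 8), bool)
        m[:4] = True  # bottom half of every 8³ cube region
        mask = BinaryBiovolume(m, iso1)
        grid = build_cube_grid(mask, 8.0)
        table = assign_voxels(mask, grid)
        quantify_geometry(table, mask, compute_distance_fields(mask))
        assert table.df["fill_fraction"].iloc[0] == pytest.approx(0.5)

    def test_uniform_slab_local_thickness(self, iso1):
        m = np.zeros((12, 16, 16), bool)
        m[:8] = True  # 8 µm slab
        mask = BinaryBiovolume(m, iso1)
        grid = build_cube_grid(mask, 4.0)
        table = assign_voxels(mask, grid)
        quantify_geometry(table, mask, compute_distance_fields(mask))
        np.testing.assert_allclose(table.df["local_thickness_um"], 8.0)

    def test_biovolume_conservation(self, hemisphere):
        grid = build_cube_grid(hemisphere, 1.0)
        table = assign_voxels(hemisphere, grid)
        quantify_geometry(table, hemisphere, compute_distance_fields(hemisphere))
        assert table.df["biovolume_um3"].sum() == pytest.approx(
            hemisphere.biovolume_um3, rel=1e-12
        )


class TestIntensityParameters:
    def _table_with_channel(self, iso1, values):
        m = np.zeros((2, 2, 2), bool)
        flat = np.zeros(8)
        flat[: len(values)] = values
        m.ravel()[: len(values)] = True
        mask = BinaryBiovolume(m, iso1)
        grid = build_cube_grid(mask, 2.0)
        table = assign_voxels(mask, grid)
        stack = IntensityStack(flat.reshape(2, 2, 2), iso1, channel_name="1")
        quantify_intensity(table, [stack])
        return table

    def test_constant_cube(self, iso1):
        t = self._table_with_channel(iso1, [100.0] * 8)
        row = t.df.iloc[0]
        assert row["ch1_mean"] == 100.0
        assert row["ch1_sd"] == 0.0
        assert row["ch1_cv"] == 0.0
        assert row["ch1_range"] == 0.0

    def test_hand_arithmetic(self, iso1):
        t = self._table_with_channel(iso1, [1.0, 2.0, 3.0, 4.0])
        row = t.df.iloc[0]
        assert row["ch1_mean"] == pytest.approx(2.5)
        assert row["ch1_median"] == pytest.approx(2.5)
        assert row["ch1_sum"] == pytest.approx(10.0)
        assert row["ch1_range"] == pytest.approx(3.0)
        assert row["ch1_sd"] == pytest.approx(np.std([1, 2, 3, 4]))

    def test_single_voxel_cube_conventions(self, iso1):
        t = self._table_with_channel(iso1, [42.0])
        row = t.df.iloc[0]
        assert row["ch1_sd"] == 0.0
        assert row["ch1_cv"] == 0.0  # mean > 0


class TestTextureParameters:
    def test_constant_cube_degenerate_glcm(self, iso1):
        m = np.ones((2, 2, 2), bool)
        mask = BinaryBiovolume(m, iso1)
        grid = build_cube_grid(mask, 2.0)
        table = assign_voxels(mask, grid)
        stack = IntensityStack(np.full((2, 2, 2), 7.0), iso1, channel_name="1")
        quantify_texture(table, [stack])
        row = table.df.iloc[0]
        assert row["ch1_glcm_energy"] == 1.0
        assert row["ch1_glcm_contrast"] == 0.0
        assert row["ch1_glcm_homogeneity"] == 1.0
        assert row["ch1_glcm_entropy"] == 0.0
        assert np.isnan(row["ch1_glcm_correlation"])

    def test_hand_enumerated_pairs_2x2x2(self, iso1):
        # two intensity levels arranged so the pair counts are enumerable
        vals = np.array(
            [[[0.0, 0.0], [10.0, 10.0]], [[0.0, 0.0], [10.0, 10.0]]]
        )  # (z, y, x): level depends on y only
        m = np.ones((2, 2, 2), bool)
        mask = BinaryBiovolume(m, iso1)
        table = assign_voxels(mask, build_cube_grid(mask, 2.0))
        quantify_texture(table, [IntensityStack(vals, iso1, channel_name="1")], levels=2)
        # ordered pairs: z-offset 4 (0,0)+4 (1,1) doubled symmetric = irrelevant
        # manual count: along z: 4 pairs (0,0),(1,1) each matching same level;
        # along y: 4 pairs crossing levels; along x: 4 pairs same level
        # symmetric counts: same-level = (4+4)*2 = 16, cross = 4*2 = 8
        p = np.array([[8.0, 4.0], [4.0, 8.0]]) / 24.0
        stats = _glcm_stats(p)
        row = table.df.iloc[0]
        for name, expected in stats.items():
            assert row[f"ch1_glcm_{name}"] == pytest.approx(expected), name

    def test_small_cube_is_nan(self, iso1):
        m = np.zeros((2, 2, 2), bool)
        m.ravel()[:4] = True  # 4 voxels < 8
        mask = BinaryBiovolume(m, iso1)
        table = assign_voxels(mask, build_cube_grid(mask, 2.0))
        quantify_texture(table, [IntensityStack(np.ones((2, 2, 2)), iso1)])
        assert np.isnan(table.df.iloc[0]["ch1_glcm_contrast"])


class TestCorrelationParameters:
    def _two_channel_cube(self, iso1, a_vals, b_vals):
        m = np.ones((2, 2, 2), bool)
        mask = BinaryBiovolume(m, iso1)
        table = assign_voxels(mask, build_cube_grid(mask, 2.0))
        a = IntensityStack(np.array(a_vals, float).reshape(2, 2, 2), iso1, channel_name="1")
        b = IntensityStack(np.array(b_vals, float).reshape(2, 2, 2), iso1, channel_name="2")
        quantify_correlations(table, [a, b])
        return table.df.iloc[0]

    def test_identical_channels(self, iso1):
        v = [1, 5, 3, 8, 2, 9, 4, 7]
        row = self._two_channel_cube(iso1, v, v)
        assert row["ch12_pearson"] == pytest.approx(1.0)
        assert row["ch12_spearman"] == pytest.approx(1.0)
        assert row["ch12_moc"] == pytest.approx(1.0)

    def test_anticorrelated_positive_channels(self, iso1):
        a = np.array([1, 2, 3, 4, 5, 6, 7, 8], float)
        b = 10.0 - a
        row = self._two_channel_cube(iso1, a, b)
        assert row["ch12_pearson"] == pytest.approx(-1.0)
        expected_moc = (a * b).sum() / np.sqrt((a**2).sum() * (b**2).sum())
        assert row["ch12_moc"] == pytest.approx(expected_moc)
        assert row["ch12_moc"] < 1.0

    def test_constant_channel_conventions(self, iso1):
        a = [5.0] * 8
        b = [1, 2, 3, 4, 5, 6, 7, 8]
        row = self._two_channel_cube(iso1, a, b)
        assert np.isnan(row["ch12_pearson"])
        assert not np.isnan(row["ch12_moc"])  # moc well-defined

    def test_density_correlation_tracks_constructed_coupling(self, fine):
        # intensity proportional to local fill -> density_corr ≈ 1 on
        # interior cubes with enough occupied neighbors
        spec = SynthSpec(
            shape="hemisphere", volume_voxels=(40, 80, 80), geometry=fine,
            seed=5, radius_um=8.0,
        )
        mask = make_colony(spec)
        grid = build_cube_grid(mask, 1.0)
        table = assign_voxels(mask, grid)
        fields = compute_distance_fields(mask)
        quantify_geometry(table, mask, fields)
        # channel = fill fraction of the cube painted onto its voxels
        fill_map = np.zeros(mask.shape)
        sel = table.assignment >= 0
        fill_map[sel] = table.df["fill_fraction"].to_numpy()[table.assignment[sel]]
        stack = IntensityStack(fill_map * 100.0, fine, channel_name="1")
        quantify_intensity(table, [stack])
        quantify_correlations(table, [stack])
        vals = table.df["ch1_density_corr"]
        interior = table.df["fill_fraction"] < 1.0  # surface cubes vary in fill
        assert vals[interior].dropna().median() > 0.9


class TestNeighborhoodParameters:
    def _quantified_block(self, iso1, m):
        mask = BinaryBiovolume(m, iso1)
        grid = build_cube_grid(mask, 2.0)
        table = assign_voxels(mask, grid)
        fields = compute_distance_fields(mask)
        quantify_geometry(table, mask, fields)
        quantify_neighborhood(table, fields)
        return table

    def test_interior_cube_of_solid_block(self, iso1):
        table = self._quantified_block(iso1, np.ones((6, 6, 6), bool))
        interior = table.df[
            (table.df["i"] == 1) & (table.df["j"] == 1) & (table.df["k"] == 1)
        ].iloc[0]
        assert interior["occupied_neighbor_count"] == 26
        assert interior["neighborhood_mean_fill"] == pytest.approx(1.0)
        assert interior["fill_gradient_magnitude"] == pytest.approx(0.0)

    def test_isolated_cube(self, iso1):
        m = np.zeros((6, 6, 6), bool)
        m[:2, :2, :2] = True
        table = self._quantified_block(iso1, m)
        row = table.df.iloc[0]
        assert row["occupied_neighbor_count"] == 0
        assert np.isnan(row["neighborhood_mean_fill"])

    def test_linear_fill_ramp_gradient(self, iso1):
        # fill fraction ramps along x: cube at i has fill (i+1)/8
        m = np.zeros((2, 2, 16), bool)
        for i in range(8):
            n_vox = (i + 1)  # of 8 voxels per 2x2x2 cube region
            region = np.zeros(8, bool)
            region[:n_vox] = True
            m[:, :, 2 * i : 2 * i + 2] = region.reshape(2, 2, 2)
        table = self._quantified_block(iso1, m)
        # interior cubes: central difference of fill = (1/8) per 2 µm step
        slope = (1 / 8) / 2.0
        interior = table.df[(table.df["i"] > 0) & (table.df["i"] < 7)]
        np.testing.assert_allclose(
            interior["fill_gradient_magnitude"], slope, atol=1e-12
        )


class TestCustomParameters:
    def _basic_table(self, iso1):
        m = np.ones((2, 2, 2), bool)
        mask = BinaryBiovolume(m, iso1)
        table = assign_voxels(mask, build_cube_grid(mask, 2.0))
        table.add_parameter("ch1_mean", [50.0])
        table.add_parameter("ch2_mean", [100.0])
        table.add_parameter("fill_fraction", [0.5])
        table.add_parameter("biovolume_um3", [0.0])
        return table

    def test_ratio(self, iso1):
        t = self._basic_table(iso1)
        add_custom_parameter(t, "ratio", "ch1_mean / ch2_mean")
        assert t.df["ratio"].iloc[0] == pytest.approx(0.5)
        assert "ratio" in t.parameters

    def test_log_of_zero_is_nan(self, iso1):
        t = self._basic_table(iso1)
        add_custom_parameter(t, "logv", "log10(biovolume_um3)")
        assert np.isnan(t.df["logv"].iloc[0])

    def test_power_and_literal(self, iso1):
        t = self._basic_table(iso1)
        add_custom_parameter(t, "p", "fill_fraction^2 + 1")
        assert t.df["p"].iloc[0] == pytest.approx(1.25)

    def test_parse_error_reports_position(self, iso1):
        with pytest.raises(ParseError, match="position"):
            ParamExpression("ch1_mean + * 2")

    def test_unknown_identifier_suggests_near_match(self, iso1):
        t = self._basic_table(iso1)
        with pytest.raises(ConfigurationError, match="ch1_mean"):
            add_custom_parameter(t, "x", "ch1_maen + 1")

    def test_division_by_zero_is_nan(self, iso1):
        t = self._basic_table(iso1)
        add_custom_parameter(t, "bad", "ch1_mean / biovolume_um3")
        assert np.isnan(t.df["bad"].iloc[0])

    def test_unary_minus_and_unicode_operators(self, iso1):
        t = self._basic_table(iso1)
        add_custom_parameter(t, "u", "-fill_fraction × 2 ÷ 4")
        assert t.df["u"].iloc[0] == pytest.approx(-0.25)


class TestGating:
    def _table_with_fills(self, iso1, fills):
        m = np.zeros((2, 2, 2 * len(fills)), bool)
        m[0, 0, : len(fills)] = True
        mask = BinaryBiovolume(m, iso1)
        table = assign_voxels(mask, build_cube_grid(mask, 1.0))
        table.add_parameter("fill_fraction", fills)
        return table

    def test_inclusive_range(self, iso1):
        t = self._table_with_fills(iso1, [0.2, 0.5, 0.9])
        out = gate(t, Gate.from_ranges(("fill_fraction", 0.5, 1.0)))
        assert len(out) == 2

    def test_invalid_bounds(self):
        with pytest.raises(ConfigurationError, match="lower"):
            RangePredicate("p", 2.0, 1.0)

    def test_empty_gate_warns(self, iso1):
        t = self._table_with_fills(iso1, [0.2, 0.5])
        with pytest.warns(UserWarning, match="no records"):
            out = gate(t, Gate.from_ranges(("fill_fraction", 0.95, 1.0)))
        assert len(out) == 0

    def test_gate_and_complement_partition_non_nan(self, iso1):
        t = self._table_with_fills(iso1, [0.1, 0.4, np.nan, 0.8])
        g = Gate.from_ranges(("fill_fraction", 0.3, 1.0))
        inside = gate(t, g)
        outside = gate(t, g, complement=True)
        assert len(inside) + len(outside) == 3  # NaN excluded from both
        ids = set(inside.df["cube_id"]) | set(outside.df["cube_id"])
        non_nan = t.df[~t.df["fill_fraction"].isna()]["cube_id"]
        assert ids == set(non_nan)

    def test_two_thickness_slab_splits_on_local_thickness(self, iso1):
        # base slab 4 µm thick with an 8 µm wrinkle ridge over half the field
        spec = SynthSpec(
            shape="slab_with_wrinkle", volume_voxels=(12, 16, 32),
            geometry=iso1, seed=1, thickness_um=4.0,
            wrinkle_thickness_um=8.0, wrinkle_x_um=(16.0, 32.0),
        )
        mask = make_colony(spec)
        grid = build_cube_grid(mask, 2.0)
        table = assign_voxels(mask, grid)
        quantify_geometry(table, mask, compute_distance_fields(mask))
        thick = gate(table, Gate.from_ranges(("local_thickness_um", 6.0, np.inf)))
        thin = gate(table, Gate.from_ranges(("local_thickness_um", 0.0, 6.0)))
        # the gate reproduces the constructed regions exactly
        assert (thick.df["centroid_x_um"] > 16.0).all()
        assert (thin.df["centroid_x_um"] < 16.0).all()
        assert len(thick) + len(thin) == len(table)


class TestParameterCount:
    def test_two_channel_parameter_total_is_49(self, two_channel_hemisphere):
        mask, stacks = two_channel_hemisphere
        grid = build_cube_grid(mask, 1.0)
        table = assign_voxels(mask, grid)
        quantify_all(table, mask, stacks)
        assert len(table.parameters) == len(set(table.parameters)) == 49

    def test_bounded_parameters_stay_in_range(self, two_channel_hemisphere):
        mask, stacks = two_channel_hemisphere
        grid = build_cube_grid(mask, 1.0)
        table = assign_voxels(mask, grid)
        quantify_all(table, mask, stacks)
        fill = table.df["fill_fraction"]
        assert ((fill >= 0) & (fill <= 1)).all()
        for c in ("ch12_pearson", "ch12_spearman", "ch1_density_corr"):
            v = table.df[c].dropna()
            assert ((v >= -1 - 1e-12) & (v <= 1 + 1e-12)).all()
        moc = table.df["ch12_moc"].dropna()
        assert ((moc >= 0) & (moc <= 1 + 1e-12)).all()
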