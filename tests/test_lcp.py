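import numpy as np
import pytest

from lcpkit.ensemble import ConformationEnsemble
from lcpkit.lcp import classify_regions, compute_lcp, lcp_summary, render_lcp

from conftest import random_ensemble, straight_chain


def brute_force_lcp(coords: np.ndarray, window: int) -> np.ndarray:
    """Independent per-frame, per-window double loop."""
    n_frames, n_res, _ = coords.shape
    n_win = n_res - window + 1
    out = np.empty((n_frames, n_win))
    for t in range(n_frames):
        for i in range(n_win):
            a = coords[t, i]
            b = coords[t, i + window - 1]
            out[t, i] = np.sqrt(((a - b) ** 2).sum())
    return out


class TestComputeLCP:
    def test_collinear_closed_form(self):
        ens = straight_chain(100, n_frames=2)
        res = compute_lcp(ens, window=75)
        assert res.n_windows == 100 - 75 + 1
        np.testing.assert_allclose(res.distances, 74 * 3.8, atol=1e-12)

    def test_window_two_reduces_to_bond_lengths(self):
        ens = random_ensemble(4, 30, seed=3)
        res = compute_lcp(ens, window=2)
        expected = np.linalg.norm(np.diff(ens.coords, axis=1), axis=2)
        np.testing.assert_allclose(res.distances, expected, atol=1e-12)

    @pytest.mark.parametrize("n_frames,n_res,window", [(5, 200, 75), (10, 300, 75), (3, 80, 10)])
    def test_matches_brute_force_oracle(self, n_frames, n_res, window):
        ens = random_ensemble(n_frames, n_res, seed=n_res)
        res = compute_lcp(ens, window=window)
        np.testing.assert_allclose(
            res.distances, brute_force_lcp(ens.coords, window), atol=1e-9
        )

    def test_window_measures_start_and_start_plus_w_minus_1(self):
        ens = random_ensemble(1, 20, seed=1)
        res = compute_lcp(ens, window=5)
        d = np.linalg.norm(ens.coords[0, 3] - ens.coords[0, 3 + 4])
        assert res.window_starts[3] == 4  # residue ids are 1-based
        assert res.distances[0, 3] == pytest.approx(d, abs=1e-12)

    def test_chain_path_upper_bound(self):
        ens = random_ensemble(5, 60, seed=9)
        res = compute_lcp(ens, window=20)
        bonds = np.linalg.norm(np.diff(ens.coords, axis=1), axis=2)
        bound = 19 * bonds.max(axis=1, keepdims=True)
        assert np.all(res.distances <= bound + 1e-9)

    def test_rigid_transform_invariance(self, rng):
        from scipy.spatial.transform import Rotation

        ens = random_ensemble(4, 90, seed=5)
        rot = Rotation.random(rng=rng).as_matrix()
        moved = ConformationEnsemble(
            ens.residue_ids,
            ens.sequence,
            ens.coords @ rot.T + np.array([11.0, -5.0, 3.0]),
        )
        np.testing.assert_allclose(
            compute_lcp(moved, 30).distances,
            compute_lcp(ens, 30).distances,
            atol=1e-9,
        )

    def test_collinear_distance_increases_with_window(self):
        ens = straight_chain(80)
        prev = 0.0
        for w in (2, 10, 40, 80):
            d = compute_lcp(ens, w).distances[0, 0]
            assert d > prev
            prev = d

    def test_window_errors(self):
        ens = random_ensemble(1, 10)
        with pytest.raises(ValueError, match="exceeds chain length"):
            compute_lcp(ens, window=11)
        with pytest.raises(ValueError, match=">= 2"):
            compute_lcp(ens, window=1)

    def test_numbering_gap_rejected(self):
        coords = np.zeros((1, 4, 3))
        coords[0, :, 0] = [0, 3.8, 7.6, 11.4]
        gapped = ConformationEnsemble(
            residue_ids=[1, 2, 5, 6], sequence="AAAA", coords=coords
        )
        with pytest.raises(ValueError, match="gaps"):
            compute_lcp(gapped, window=2)


class TestSummary:
    def test_single_frame_degenerate(self):
        ens = random_ensemble(1, 30, seed=2)
        table = lcp_summary(compute_lcp(ens, 10))
        np.testing.assert_allclose(table["mean"], table["min"])
        np.testing.assert_allclose(table["mean"], table["max"])
        np.testing.assert_allclose(table["sd"], 0.0)

    def test_constant_ensemble_summary(self, straight75):
        table = lcp_summary(compute_lcp(straight75, 75))
        np.testing.assert_allclose(table["mean"], 281.2, atol=1e-9)
        np.testing.assert_allclose(table["sd"], 0.0, atol=1e-12)

    def test_two_state_mean(self):
        ens1 = straight_chain(40, n_frames=2, spacing=3.8)
        ens2 = straight_chain(40, n_frames=2, spacing=2.0)
        mixed = ConformationEnsemble(
            ens1.residue_ids,
            ens1.sequence,
            np.concatenate([ens1.coords, ens2.coords]),
        )
        table = lcp_summary(compute_lcp(mixed, 40))
        d1, d2 = 39 * 3.8, 39 * 2.0
        assert table["mean"][0] == pytest.approx((d1 + d2) / 2, abs=1e-9)

    def test_percentile_validation(self):
        res = compute_lcp(random_ensemble(2, 10), 5)
        with pytest.raises(ValueError, match="outside"):
            lcp_summary(res, percentiles=[1.5])
        assert list(lcp_summary(res, percentiles=[]).columns) == [
            "window_start", "window_center", "mean", "sd", "min", "max",
        ]


class TestClassification:
    def test_everything_below_threshold_is_compact(self):
        ens = random_ensemble(10, 40, seed=8, scale=8.0)  # distances < ~30 Å
        cls = classify_regions(compute_lcp(ens, 20))
        assert set(cls.residue_labels.values()) == {"compact"}

    def test_extended_chain_is_extended(self):
        ens = straight_chain(100, n_frames=4)
        cls = classify_regions(compute_lcp(ens, 75))  # 281.2 Å >> 50 Å
        assert set(cls.residue_labels.values()) == {"extended"}

    def test_intermediate_band(self):
        ens = straight_chain(30, n_frames=1, spacing=3.0)  # 29 bonds: 87 Å end-to-end
        cls = classify_regions(compute_lcp(ens, 30), compact_max=50, extended_min=120)
        assert set(cls.residue_labels.values()) == {"intermediate"}

    def test_threshold_validation(self):
        res = compute_lcp(random_ensemble(2, 10), 5)
        with pytest.raises(ValueError, match="<="):
            classify_regions(res, compact_max=60, extended_min=50)
        with pytest.raises(ValueError, match="positive"):
            classify_regions(res, compact_max=-1, extended_min=50)

    def test_labels_cover_all_windowed_residues(self):
        ens = random_ensemble(3, 50, seed=4)
        cls = classify_regions(compute_lcp(ens, 20))
        assert sorted(cls.residue_labels) == list(range(1, 51))


class TestRender:
    def test_writes_figure(self, tmp_path, straight75):
        res = compute_lcp(straight75, 75)
        out = render_lcp(res, tmp_path / "lcp.png", alpha=0.5)
        assert out.exists() and out.stat().st_size > 0

    def test_density_mode_and_reference_trace(self, tmp_path):
        res = compute_lcp(random_ensemble(5, 90, seed=6), 75)
        out = render_lcp(res, tmp_path / "lcp.svg", mode="density", reference_frame=0)
        assert out.exists()

    def test_majority_conformation_renders_darker(self, tmp_path):
        """90%/10% two-state mixture: the majority distance band accumulates
        more opacity than the minority band."""
        import matplotlib

        matplotlib.use("Agg")
        import matplotlib.pyplot as plt

        n = 40
        a = straight_chain(n, n_frames=9, spacing=3.8)
        b = straight_chain(n, n_frames=1, spacing=2.0)
        mixed = ConformationEnsemble(
            a.residue_ids, a.sequence, np.concatenate([a.coords, b.coords])
        )
        res = compute_lcp(mixed, n)
        out = render_lcp(res, tmp_path / "mix.png", alpha=0.1)
        lum = plt.imread(out)[..., :3].mean(axis=2)
        # nine overlaid points at alpha 0.1 accumulate ~0.61 opacity (dark
        # band, luminance ~0.4); a single point stays at 0.1 (~0.9). Both
        # bands span the plot width, so each contributes hundreds of pixels.
        dark_band = ((lum > 0.25) & (lum < 0.55)).sum()
        light_band = ((lum > 0.82) & (lum < 0.95)).sum()
        assert dark_band > 300
        assert light_band > 300

    def test_alpha_and_mode_validation(self, tmp_path, straight75):
        res = compute_lcp(straight75, 75)
        with pytest.raises(ValueError, match="alpha"):
            render_lcp(res, tmp_path / "x.png", alpha=0.0)
        with pytest.raises(ValueError, match="mode"):
            render_lcp(res, tmp_path / "x.png", mode="hexbin")
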