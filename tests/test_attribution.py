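"""VIF screening, boosted-tree attribution and SHAP consistency."""

import numpy as np
import pandas as pd
import pytest

from isowue.attribution import (
    fit_attribution,
    rank_report,
    vif_screen,
)


def _orthonormal_pair(n=200, seed=0):
    rng = np.random.default_rng(seed)
    a = rng.normal(size=n)
    b = rng.normal(size=n)
    a = (a - a.mean()) / a.std()
    b = b - b.mean()
    b -= (b @ a) / (a @ a) * a  # exactly orthogonal in sample
    b /= b.std()
    return a, b


class TestVifScreen:
    def test_orthogonal_features_all_retained(self):
        a, b = _orthonormal_pair()
        fs = vif_screen(pd.DataFrame({"f1": a, "f2": b}), ["f1", "f2"])
        assert fs.retained == ["f1", "f2"]
        for v in fs.final_vif.values():
            assert v == pytest.approx(1.0, abs=1e-9)

    def test_exact_duplicate_dropped(self):
        a, b = _orthonormal_pair()
        df = pd.DataFrame({"f1": a, "f1_copy": a.copy(), "f2": b})
        fs = vif_screen(df, ["f1", "f1_copy", "f2"])
        assert fs.retained == ["f1", "f2"]     # alphabetically-last twin dropped
        assert "f1_copy" in fs.dropped

    def test_known_correlation_vif_value(self):
        # construct an exact sample correlation of 0.8: VIF = 1/(1−0.64) = 2.78
        a, b = _orthonormal_pair()
        x2 = 0.8 * a + np.sqrt(1 - 0.64) * b
        c = np.sin(np.arange(len(a)))  # effectively independent third feature
        fs = vif_screen(
            pd.DataFrame({"x1": a, "x2": x2, "x3": c}), ["x1", "x2", "x3"],
            threshold=10.0,
        )
        assert fs.final_vif["x1"] == pytest.approx(2.78, abs=0.05)
        assert fs.final_vif["x2"] == pytest.approx(2.78, abs=0.05)
        assert fs.retained == ["x1", "x2", "x3"]

    def test_column_order_independence(self, iwue_table):
        sub = iwue_table[iwue_table.pathway == "C3"]
        feats = ["elevation_m", "mat_c", "map_mm", "vpd_kpa", "ai",
                 "leaf_n", "leaf_p", "soil_cn"]
        base = vif_screen(sub, feats)
        rng = np.random.default_rng(0)
        for _ in range(3):
            perm = list(rng.permutation(feats))
            assert set(vif_screen(sub, perm).retained) == set(base.retained)

    def test_all_retained_below_threshold(self, iwue_table):
        sub = iwue_table[iwue_table.pathway == "C3"]
        fs = vif_screen(sub, threshold=10.0)
        assert fs.retained
        assert all(v < 10.0 for v in fs.final_vif.values())

    def test_too_few_rows_or_features(self):
        with pytest.raises(ValueError):
            vif_screen(pd.DataFrame({"a": [1.0, 2.0]}), ["a"])


def _single_driver_frame(seed, n=300, noise=0.1):
    rng = np.random.default_rng(seed)
    x = pd.DataFrame(
        {f"f{j}": rng.normal(size=n) for j in range(5)}
    )
    y = 3.0 * x["f2"] + noise * rng.normal(size=n)
    x["resp"] = y
    return x


class TestAttribution:
    def test_single_driver_ranks_first(self):
        df = _single_driver_frame(seed=0)
        res = fit_attribution(df, [f"f{j}" for j in range(5)], "resp", seed=0)
        assert res.ranking[0] == "f2"
        assert res.dependence_sign["f2"] == 1

    def test_shap_additivity(self):
        """Per observation, SHAP contributions plus the base value must
        reconstruct the model prediction exactly (explainer consistency)."""
        df = _single_driver_frame(seed=1)
        feats = [f"f{j}" for j in range(5)]
        res = fit_attribution(df, feats, "resp", seed=1)
        recon = res.shap_values.sum(axis=1) + res.base_value
        assert np.allclose(recon, res.predictions, atol=1e-4)

    def test_dependence_signs_match_generator_truth(self, iwue_table,
                                                    default_transect):
        """VPD dependence: negative for C3, positive for C4, matching the
        direction implied by the generator's trend structure."""
        _, truth = default_transect
        feats = ["vpd_kpa", "leaf_n", "leaf_p", "soil_cn", "sr", "shannon"]
        for pathway in ("C3", "C4"):
            sub = iwue_table[iwue_table.pathway == pathway]
            res = fit_attribution(sub, feats, "iWUE", seed=2)
            assert (
                res.dependence_sign["vpd_kpa"]
                == truth.attribution_signs[pathway]["vpd_kpa"]
            ), pathway

    def test_constant_response_rejected(self):
        df = _single_driver_frame(seed=2)
        df["resp"] = 1.0
        with pytest.raises(ValueError, match="constant"):
            fit_attribution(df, ["f0", "f1"], "resp", seed=0)

    def test_empty_features_rejected(self):
        df = _single_driver_frame(seed=2)
        with pytest.raises(ValueError, match="empty"):
            fit_attribution(df, [], "resp", seed=0)

    def test_determinism_same_seed(self):
        df = _single_driver_frame(seed=3)
        feats = [f"f{j}" for j in range(5)]
        r1 = fit_attribution(df, feats, "resp", seed=7)
        r2 = fit_attribution(df, feats, "resp", seed=7)
        assert r1.importance == r2.importance
        assert r1.ranking == r2.ranking


class TestRankReport:
    def _fake_result(self, importances):
        from isowue.attribution import AttributionResult

        feats = list(importances)
        return AttributionResult(
            response="y", features=feats, importance=importances,
            ranking=sorted(feats, key=lambda f: (-importances[f], f)),
            dependence_sign={f: 1 for f in feats},
            dependence_rho={f: 0.5 for f in feats},
            shap_values=np.zeros((2, len(feats))), predictions=np.zeros(2),
            base_value=0.0, seed=0,
        )

    def test_tie_order_alphabetical(self, tmp_path):
        res = self._fake_result({"b": 1.0, "a": 1.0, "c": 1.0})
        report = rank_report(res, tmp_path)
        assert report["feature"].tolist() == ["a", "b", "c"]
        assert (tmp_path / "importance.csv").exists()

    def test_top_k_exceeding_feature_count(self):
        res = self._fake_result({"a": 2.0, "b": 1.0})
        report = rank_report(res, top_k=10)
        assert len(report) == 2

    def test_rerun_identical_file(self, tmp_path):
        res = self._fake_result({"a": 2.0, "b": 1.0})
        rank_report(res, tmp_path / "r1")
        rank_report(res, tmp_path / "r2")
        assert (tmp_path / "r1" / "importance.csv").read_bytes() == (
            tmp_path / "r2" / "importance.csv"
        ).read_bytes()
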