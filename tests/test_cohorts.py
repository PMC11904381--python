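"""Synthetic cohort generator: published parameters, sampling laws, CSV I/O."""

import numpy as np
import pytest
from scipy import stats

import sepsiscreen as ss
from sepsiscreen.cohorts import CohortSpecError, TableParseError


class TestBuiltinSpecs:
    def test_six_cohorts_present(self, builtin_specs):
        assert sorted(builtin_specs) == sorted(
            ["PA-ED", "AR-ED", "PA-ICU", "PD-ICU", "UD-ED", "OGSA-ICU"])

    @pytest.mark.parametrize("cid,n,prev", [
        ("PA-ED", 1809, 0.0459),
        ("AR-ED", 308, 0.247),
        ("PA-ICU", 75, 0.29),
        ("PD-ICU", 2114, 0.3354),
        ("UD-ED", 938, 0.067),
        ("OGSA-ICU", 100, 0.06),
    ])
    def test_published_sizes_and_prevalences(self, builtin_specs, cid, n, prev):
        assert builtin_specs[cid].n == n
        assert builtin_specs[cid].prevalence == pytest.approx(prev, abs=1e-12)

    @pytest.mark.parametrize("cid,feature,mean,sd", [
        ("PA-ED", "mdw", 20.1, 3.2),
        ("PA-ED", "crp", 22.6, 49.3),
        ("PA-ED", "age", 55.1, 20.0),
        ("AR-ED", "mdw", 25.6, 6.4),
        ("PA-ICU", "rdw", 48.0, 7.6),
        ("PD-ICU", "plt", 236.7, 145.3),
        ("UD-ED", "nlr", 5.8, 7.1),
        # printed as-is even though physiologically anomalous
        ("OGSA-ICU", "mchc", 66.1, 327.5),
    ])
    def test_published_feature_moments(self, builtin_specs, cid, feature, mean, sd):
        fs = builtin_specs[cid].features[feature]
        assert (fs.mean, fs.sd) == (mean, sd)

    def test_sex_proportions(self, builtin_specs):
        assert builtin_specs["PA-ED"].features["sex"].mean == pytest.approx(0.4859)
        assert builtin_specs["PD-ICU"].features["sex"].mean == pytest.approx(0.7625)

    def test_ogsa_mdw_fully_missing(self, builtin_specs):
        assert builtin_specs["OGSA-ICU"].missingness["mdw"] == 1.0

    def test_all_specs_validate(self, builtin_specs):
        for spec in builtin_specs.values():
            spec.validate()


class TestSpecValidation:
    def test_bad_field_named_in_error(self, builtin_specs):
        with pytest.raises(CohortSpecError, match="prevalence"):
            ss.generate_cohort(builtin_specs["PA-ED"].replace(prevalence=1.5))
        with pytest.raises(CohortSpecError, match="n must be"):
            ss.generate_cohort(builtin_specs["PA-ED"].replace(n=5))
        with pytest.raises(CohortSpecError, match="missingness"):
            ss.generate_cohort(
                builtin_specs["PA-ED"].replace(missingness={"mdw": 1.2}))
        with pytest.raises(CohortSpecError, match="label_noise"):
            ss.generate_cohort(builtin_specs["PA-ED"].replace(label_noise=1.0))


class TestGeneration:
    def test_deterministic(self, builtin_specs):
        spec = builtin_specs["UD-ED"].replace(n=300)
        a = ss.generate_cohort(spec)
        b = ss.generate_cohort(spec)
        assert a.equals(b)

    def test_prevalence_within_binomial_band(self, builtin_specs):
        spec = builtin_specs["PA-ED"].replace(n=1000, seed=7)
        t = ss.generate_cohort(spec)
        lo, hi = stats.binom.interval(0.99, 1000, 0.0459)
        assert lo <= t.labels.sum() <= hi

    def test_no_shift_means_match_reference(self, builtin_specs):
        # restricted to features whose floor sits >~2.5 SD below the mean:
        # for strongly skewed features (e.g. CRP, SD > mean) the truncation
        # at zero necessarily raises the mean above the printed location
        spec = builtin_specs["PA-ED"].replace(
            n=4000, effect_sizes={}, label_noise=0.0, seed=11)
        t = ss.generate_cohort(spec)
        for name in ("mdw", "wbc", "plt", "hgb", "rbc"):
            fs = spec.features[name]
            for cls in (0, 1):
                rows = t.labels == cls
                tol = 4 * fs.sd / np.sqrt(rows.sum())
                assert abs(t.column(name)[rows].mean() - fs.mean) < tol

    def test_class_conditional_mdw_shift(self, builtin_specs):
        spec = builtin_specs["PA-ED"].replace(
            n=4000, prevalence=0.3, label_noise=0.0,
            effect_sizes={"mdw": 2.0}, seed=3)
        t = ss.generate_cohort(spec)
        sd = spec.features["mdw"].sd
        gap = (t.column("mdw")[t.labels == 1].mean()
               - t.column("mdw")[t.labels == 0].mean())
        assert abs(gap - 2 * sd) < 0.2 * sd

    def test_full_missingness_masks_only_that_column(self, builtin_specs):
        t = ss.generate_cohort(builtin_specs["OGSA-ICU"])
        assert t.column_mask("mdw").all()
        others = [c for c in t.columns if c != "mdw"]
        assert not any(t.column_mask(c).any() for c in others)

    def test_partial_missingness_within_binomial_band(self, builtin_specs):
        spec = builtin_specs["PA-ED"].replace(n=2000, missingness={"crp": 0.3}, seed=5)
        t = ss.generate_cohort(spec)
        lo, hi = stats.binom.interval(0.99, 2000, 0.3)
        assert lo <= t.column_mask("crp").sum() <= hi

    def test_nlr_functional_dependence(self, planted_cohort):
        t = planted_cohort
        np.testing.assert_allclose(
            t.column("nlr"), t.column("neutrophils") / t.column("lymphocytes"),
            rtol=1e-9)

    def test_label_noise_flips_borderline_rows(self, builtin_specs):
        base = builtin_specs["PA-ED"].replace(n=1000, seed=9, label_noise=0.0)
        noisy = base.replace(label_noise=0.05)
        t0 = ss.generate_cohort(base)
        t1 = ss.generate_cohort(noisy)
        flipped = np.nonzero(t0.labels != t1.labels)[0]
        assert len(flipped) == 50
        # flipped rows sit nearer the MDW class boundary than unflipped rows
        fs = base.features["mdw"]
        boundary = fs.mean + 0.5 * base.effect_sizes["mdw"] * fs.sd
        d = np.abs(t0.column("mdw") - boundary)
        assert d[flipped].max() <= np.delete(d, flipped).min()


class TestCsvRoundTrip:
    def test_round_trip_bit_exact(self, builtin_specs, tmp_path):
        spec = builtin_specs["OGSA-ICU"].replace(missingness={"mdw": 0.5})
        t = ss.generate_cohort(spec)
        path = tmp_path / "cohort.csv"
        ss.write_table(t, path)
        assert ss.read_table(path).equals(t)

    def test_missing_label_column_rejected(self, builtin_specs, tmp_path):
        t = ss.generate_cohort(builtin_specs["PA-ED"].replace(n=20))
        path = tmp_path / "c.csv"
        ss.write_table(t, path)
        text = path.read_text().splitlines()
        text[0] = text[0].replace("sepsis", "outcome")
        path.write_text("\n".join(text))
        with pytest.raises(TableParseError, match="sepsis|unrecognized"):
            ss.read_table(path)

    def test_extra_column_listed_in_error(self, builtin_specs, tmp_path):
        t = ss.generate_cohort(builtin_specs["PA-ED"].replace(n=20))
        path = tmp_path / "c.csv"
        ss.write_table(t, path)
        lines = path.read_text().splitlines()
        lines[0] += ",mystery"
        body = [line + ",1" for line in lines[1:]]
        path.write_text("\n".join([lines[0]] + body))
        with pytest.raises(TableParseError, match="mystery"):
            ss.read_table(path)

    def test_non_numeric_cell_coordinates(self, builtin_specs, tmp_path):
        t = ss.generate_cohort(builtin_specs["PA-ED"].replace(n=20))
        path = tmp_path / "c.csv"
        ss.write_table(t, path)
        lines = path.read_text().splitlines()
        cells = lines[3].split(",")
        cells[0] = "not_a_number"
        lines[3] = ",".join(cells)
        path.write_text("\n".join(lines))
        with pytest.raises(TableParseError, match=r"row 2.*'age'"):
            ss.read_table(path)
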