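"""Random-intercept LMM: REML estimates, Satterthwaite F tests, cross-checks.

The engine is validated two ways: against R's lmerTest/emmeans (the reference
implementation of Satterthwaite inference for mixed models) on one fixed
table, and against classical repeated-measures ANOVA (pingouin) in the
balanced one-factor case where the two coincide.
"""

import json
import shutil
import subprocess
from pathlib import Path

import numpy as np
import pandas as pd
import pytest

from prfconn.lmm import fit_lmm, lmm_anova
from prfconn.stats import band_by_stream_anova, tukey_posthoc


def example_table(seed=7, n_subjects=12, missing=(3, 17, 40)):
    """Band x stream table with a built-in interaction and missing cells."""
    rng = np.random.default_rng(seed)
    rows = []
    for s in range(n_subjects):
        b0 = rng.normal(0, 0.05)
        for stream in ("ventral", "lateral"):
            for bi, band in enumerate(["b1", "b2", "b3", "b4"]):
                mu = 0.25 + (0.1 * bi if stream == "ventral" else -0.02 * bi)
                rows.append({"subject": s, "stream": stream, "band": band,
                             "value": mu + b0 + rng.normal(0, 0.08)})
    return pd.DataFrame(rows).drop(index=list(missing)).reset_index(drop=True)


@pytest.fixture(scope="module")
def r_reference(tmp_path_factory):
    tmp = tmp_path_factory.mktemp("lmer")
    example_table().to_csv(tmp / "table.csv", index=False)
    script = tmp / "ref.R"
    script.write_text("""
suppressMessages({library(lmerTest); library(emmeans)})
df <- read.csv(file.path(commandArgs(TRUE)[1], "table.csv"))
df$band <- factor(df$band); df$stream <- factor(df$stream)
df$subject <- factor(df$subject)
options(contrasts = c("contr.sum", "contr.poly"))
m <- lmer(value ~ band * stream + (1 | subject), data = df)
a <- anova(m, type = 3)
vc <- as.data.frame(VarCorr(m))
tk <- summary(emmeans(m, pairwise ~ band, lmer.df = "satterthwaite")$contrasts)
out <- list(F = a$`F value`, den_df = a$DenDF,
            sigma2_b = vc$vcov[1], sigma2_e = vc$vcov[2],
            tukey_p = tk$p.value, tukey_est = tk$estimate)
cat(jsonlite::toJSON(out, digits = 12))
""")
    res = subprocess.run([shutil.which("Rscript") or "Rscript", str(script), str(tmp)],
                         capture_output=True, text=True, timeout=300)
    assert res.returncode == 0, res.stderr
    return json.loads(res.stdout)


class TestAgainstLmerTest:
    """Live comparison with R lmerTest + emmeans on the example table."""

    def test_f_statistics_and_dfs_match(self, r_reference):
        anova = band_by_stream_anova(example_table())
        got = anova.rows.set_index("effect")
        for i, effect in enumerate(["band", "stream", "band:stream"]):
            assert got.loc[effect, "F"] == pytest.approx(r_reference["F"][i], rel=1e-4)
            assert got.loc[effect, "df2"] == pytest.approx(r_reference["den_df"][i], rel=5e-3)

    def test_variance_components_match(self, r_reference):
        fit = band_by_stream_anova(example_table()).fit
        assert fit.sigma2_b == pytest.approx(r_reference["sigma2_b"][0], rel=1e-4)
        assert fit.sigma2_e == pytest.approx(r_reference["sigma2_e"][0], rel=1e-4)

    def test_tukey_matches_emmeans(self, r_reference):
        anova = band_by_stream_anova(example_table())
        tk = tukey_posthoc(anova, "band")
        assert np.allclose(tk["estimate"], r_reference["tukey_est"], rtol=1e-4)
        assert np.allclose(tk["p_adj"], r_reference["tukey_p"], rtol=1e-3, atol=1e-6)


class TestClassicalEquivalence:
    def test_balanced_one_way_equals_rm_anova(self):
        """With one within-subject factor and complete balanced data, the
        random-intercept LMM F equals the classical RM-ANOVA F."""
        pingouin = pytest.importorskip("pingouin")
        rng = np.random.default_rng(3)
        rows = []
        for s in range(10):
            b0 = rng.normal(0, 1.0)
            for bi, band in enumerate(["b1", "b2", "b3", "b4"]):
                rows.append({"subject": s, "band": band,
                             "value": 0.1 * bi + b0 + rng.normal(0, 0.5)})
        df = pd.DataFrame(rows)
        anova = lmm_anova(df, "value", ["band"])
        classical = pingouin.rm_anova(data=df, dv="value", within="band",
                                      subject="subject")
        assert anova.effect("band")["F"] == pytest.approx(
            float(classical["F"].iloc[0]), abs=1e-6)
        assert anova.effect("band")["df2"] == pytest.approx(
            float(classical["ddof2"].iloc[0]), abs=1e-3)

    def test_tukey_classical_matches_statsmodels(self):
        """Between-group one-way data: the classical-df Tukey p-values agree
        with statsmodels' studentized-range HSD."""
        sm = pytest.importorskip("statsmodels.stats.multicomp")
        rng = np.random.default_rng(4)
        rows = []
        values, labels = [], []
        for gi, group in enumerate(["a", "b", "c"]):
            for r in range(15):
                v = gi * 0.8 + rng.normal(0, 1.0)
                rows.append({"subject": f"{group}{r}", "band": group, "value": v})
                values.append(v)
                labels.append(group)
        df = pd.DataFrame(rows)
        anova = lmm_anova(df, "value", ["band"])
        tk = tukey_posthoc(anova, "band").sort_values(["level_a", "level_b"])
        ref = sm.pairwise_tukeyhsd(np.array(values), np.array(labels))
        assert np.allclose(tk["p_adj_classical"], ref.pvalues, atol=2e-4)


class TestModelBehaviour:
    def test_additive_shift_gives_main_effect_not_interaction(self):
        rng = np.random.default_rng(5)
        rows = []
        for s in range(15):
            b0 = rng.normal(0, 0.05)
            for stream, shift in (("ventral", 0.3), ("lateral", 0.0)):
                for bi, band in enumerate(["b1", "b2", "b3", "b4"]):
                    rows.append({"subject": s, "stream": stream, "band": band,
                                 "value": 0.1 * bi + shift + b0 + rng.normal(0, 0.05)})
        anova = band_by_stream_anova(pd.DataFrame(rows))
        assert anova.effect("stream")["p"] < 1e-6
        assert anova.effect("band:stream")["p"] > 0.01

    def test_boundary_fit_flagged_singular(self):
        # antithetic within-subject values: subject means are all zero, so the
        # intercept variance is driven to the boundary
        rng = np.random.default_rng(6)
        rows = []
        for s in range(8):
            v = rng.normal()
            rows += [{"subject": s, "band": "b1", "value": v},
                     {"subject": s, "band": "b2", "value": -v}]
        fit = fit_lmm(pd.DataFrame(rows), "value", ["band"])
        assert fit.singular
        assert fit.sigma2_b < 1e-6

    def test_missing_cells_tolerated(self):
        df = example_table(missing=tuple(range(0, 30, 3)))
        anova = band_by_stream_anova(df)
        assert np.isfinite(anova.rows["F"]).all()
        assert (anova.rows["df2"] > 2).all()

    @pytest.mark.parametrize("bad", [
        pd.DataFrame({"subject": [0], "stream": ["v"], "band": ["b"], "value": [1.0]}),
    ])
    def test_insufficient_data_rejected(self, bad):
        with pytest.raises(ValueError):
            band_by_stream_anova(bad)
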