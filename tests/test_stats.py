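"""Nested random-intercept mixed models and Tukey-adjusted contrasts."""

import shutil
import subprocess
import textwrap

import numpy as np
import pandas as pd
import pytest

from ccfdgrid import (LMMError, emd_contrasts, fit_lmm, onset_contrasts,
                      summarize_tables)


def simulate_box_table(rng, n_patients=10, bilateral=3, n_boxes=5,
                       effect=(0.0, 0.0, 0.0, 0.0), sd_patient=1.2,
                       sd_eye=0.8, sd_box=2.0, sd_resid=1.5,
                       category="target"):
    """Tabular simulator with known nested variance components."""
    rows = []
    for p in range(n_patients):
        bp = rng.normal(0, sd_patient)
        for e in range(2 if p < bilateral else 1):
            be = rng.normal(0, sd_eye)
            for b in range(n_boxes):
                bb = rng.normal(0, sd_box)
                for v in range(4):
                    rows.append(dict(
                        patient_id=f"p{p}", eye_id=f"e{e}", box_id=b,
                        visit_index=v, category=category,
                        ccfd_pct=10 + bp + be + bb + effect[v]
                        + rng.normal(0, sd_resid),
                        valid_frac=1.0, included=True))
    return pd.DataFrame(rows)


class TestFitLMM:
    def test_recovers_visit_means_and_positive_components(self):
        rng = np.random.default_rng(0)
        tab = simulate_box_table(rng, effect=(0, 0, 3.0, 3.0))
        fit = fit_lmm(tab, group="target")
        assert fit.fixed_effects[2] - fit.fixed_effects[1] == pytest.approx(3.0, abs=1.0)
        assert fit.variance_components["residual"] > 0
        assert fit.n_boxes == (10 + 3) * 5

    def test_single_patient_eye_box_reduces_to_repeated_measures(self):
        rng = np.random.default_rng(1)
        rows = [dict(patient_id="p0", eye_id="e0", box_id=0, visit_index=v,
                     category="target", ccfd_pct=10 + v + rng.normal(0, 0.5),
                     valid_frac=1.0, included=True)
                for v in range(4) for _ in range(3)]
        fit = fit_lmm(pd.DataFrame(rows), group="target")
        assert set(fit.dropped_intercepts) == {"patient", "eye", "box"}

    def test_all_observations_equal_is_an_error(self):
        rows = [dict(patient_id="p0", eye_id="e0", box_id=b, visit_index=v,
                     category="target", ccfd_pct=5.0, valid_frac=1.0,
                     included=True)
                for b in range(4) for v in range(4)]
        with pytest.raises(LMMError):
            fit_lmm(pd.DataFrame(rows), group="target")

    def test_excluded_rows_are_ignored(self):
        rng = np.random.default_rng(2)
        tab = simulate_box_table(rng)
        tab.loc[tab.box_id == 0, "included"] = False
        fit = fit_lmm(tab, group="target")
        assert fit.n_boxes == (10 + 3) * 4

    def test_unidentifiable_eye_level_is_predropped(self):
        # one eye per patient: the eye intercept IS the patient intercept
        rng = np.random.default_rng(3)
        tab = simulate_box_table(rng, bilateral=0)
        fit = fit_lmm(tab, group="target")
        assert "eye" in fit.dropped_intercepts
        assert "patient" not in fit.dropped_intercepts

    def test_dropping_zero_variance_level_does_not_move_fixed_effects(self):
        from ccfdgrid.stats import _fit_once, _prepare
        rng = np.random.default_rng(3)
        tab = simulate_box_table(rng, sd_eye=0.0, bilateral=5)
        fit = fit_lmm(tab, group="target")
        df = _prepare(tab, "target")
        res_full, _ = _fit_once(df, ["patient", "eye", "box"])
        for v in range(1, 4):
            full = res_full.fe_params[f"C(visit_index)[T.{v}]"]
            ladder = fit.fixed_effects[v] - fit.fixed_effects[0]
            assert ladder == pytest.approx(full, abs=1e-6)


class TestContrasts:
    def test_balanced_no_random_effects_emd_is_mean_difference(self):
        rng = np.random.default_rng(4)
        rows = [dict(patient_id=f"p{i}", eye_id="e0", box_id=0,
                     visit_index=v, category="target",
                     ccfd_pct=float(10 + 2 * v + rng.normal(0, 0.5)),
                     valid_frac=1.0, included=True)
                for i in range(6) for v in (0, 1)]
        tab = pd.DataFrame(rows)
        fit = fit_lmm(tab, group="target")
        diff = (tab[tab.visit_index == 0].ccfd_pct.mean()
                - tab[tab.visit_index == 1].ccfd_pct.mean())
        c = [c for c in emd_contrasts(fit) if {c.visit_a, c.visit_b} == {0, 1}][0]
        emd = c.emd if (c.visit_a, c.visit_b) == (0, 1) else -c.emd
        assert emd == pytest.approx(diff, abs=1e-6)

    def test_antisymmetry_of_emd(self):
        rng = np.random.default_rng(5)
        fit = fit_lmm(simulate_box_table(rng), group="target")
        cs = {(c.visit_a, c.visit_b): c for c in emd_contrasts(fit)}
        for (a, b), c in cs.items():
            assert c.emd == pytest.approx(fit.fixed_effects[a] - fit.fixed_effects[b])
        onset = onset_contrasts(fit)
        assert [c.visit_a for c in onset] == [0, 2, 3]
        for c in onset:
            assert c.ci_low <= c.emd <= c.ci_high
            assert 0.0 <= c.p_adj <= 1.0


class TestAgainstR:
    @pytest.mark.skipif(shutil.which("Rscript") is None,
                        reason="Rscript not available")
    def test_matches_lme4_emmeans_on_shared_data(self, tmp_path):
        rng = np.random.default_rng(7)
        tab = simulate_box_table(rng, effect=(0, 0, 2.5, 2.5))
        csv = tmp_path / "tab.csv"
        tab.to_csv(csv, index=False)
        script = tmp_path / "check.R"
        script.write_text(textwrap.dedent(f"""
            suppressMessages({{library(lme4); library(emmeans)}})
            d <- read.csv("{csv}")
            d$visit <- factor(d$visit_index)
            d$eye_uid <- paste(d$patient_id, d$eye_id)
            d$box_uid <- paste(d$eye_uid, d$box_id)
            m <- lmer(ccfd_pct ~ visit + (1|patient_id) + (1|eye_uid) + (1|box_uid),
                      data=d, REML=TRUE)
            s <- summary(pairs(emmeans(m, "visit"), adjust="tukey"))
            out <- s[s$contrast == "visit0 - visit1", c("estimate","SE","p.value")]
            cat(out$estimate, out$SE, out$p.value, sep="\\n")
        """))
        res = subprocess.run(["Rscript", str(script)], capture_output=True,
                             text=True, timeout=300)
        assert res.returncode == 0, res.stderr
        est_r, se_r, p_r = (float(x) for x in res.stdout.split())

        fit = fit_lmm(tab, group="target")
        c = [c for c in emd_contrasts(fit) if (c.visit_a, c.visit_b) == (1, 0)][0]
        assert -c.emd == pytest.approx(est_r, abs=1e-4)   # visit0 - visit1
        assert c.se == pytest.approx(se_r, rel=0.02)
        assert c.p_adj == pytest.approx(p_r, abs=0.02)


class TestSummaryTables:
    def test_four_tables_with_box_counts(self):
        rng = np.random.default_rng(8)
        fits = {}
        for cat, name in (("target", "target"),
                          ("adjacent_background", "adjacent"),
                          ("nonadjacent_background", "nonadjacent")):
            fits[name] = fit_lmm(simulate_box_table(rng, category=cat),
                                 group=name)
        fits["background"] = fits["adjacent"]
        tables = summarize_tables(fits)
        assert set(tables) == {"target", "background", "adjacent", "nonadjacent"}
        t = tables["target"]
        assert list(t["comparison"]) == ["1 y prior to hyperTD onset",
                                         "1 y after hyperTD onset",
                                         "2 y after hyperTD onset"]
        assert (t["n_boxes"] == 65).all()

    def test_missing_category_warns_and_is_omitted(self):
        rng = np.random.default_rng(9)
        fits = {"target": fit_lmm(simulate_box_table(rng), group="target")}
        with pytest.warns(UserWarning, match="omitted"):
            tables = summarize_tables(fits)
        assert set(tables) == {"target"}
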