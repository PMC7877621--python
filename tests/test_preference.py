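"""Choice design, conditional-logit estimation and the preference function."""

import numpy as np
import pandas as pd
import pytest

import vaxfolio as vf
from vaxfolio._rng import substream
from vaxfolio.preference import SeparationError, design_matrix, slug


class TestDesign:
    def test_dimensions(self, levels):
        d = vf.build_design(levels, blocks=2, sets_per_block=16, alts=3,
                            rng=np.random.default_rng(0))
        assert d.n_blocks * d.sets_per_block == 32
        assert all(m.shape == (3, 5) for block in d.sets for m in block)

    def test_level_balance_within_one(self, levels):
        d = vf.build_design(levels, rng=np.random.default_rng(1))
        for platform, counts in d.diagnostics()["balance"].items():
            values = list(counts.values())
            assert max(values) - min(values) <= 1

    def test_seeded_determinism(self, levels):
        d1 = vf.build_design(levels, rng=np.random.default_rng(5))
        d2 = vf.build_design(levels, rng=np.random.default_rng(5))
        assert all(
            np.array_equal(a, b)
            for b1, b2 in zip(d1.sets, d2.sets)
            for a, b in zip(b1, b2)
        )

    def test_too_few_alternatives_rejected(self, levels):
        with pytest.raises(ValueError, match="alternatives"):
            vf.build_design(levels, alts=1, rng=np.random.default_rng(0))


class TestPreferenceWeight:
    def test_published_worked_values(self):
        # RNA at the middle level: w * pos reproduces the a->b part-worth
        w = vf.preference_weight(1.313, 0.360, (0.0, 0.30, 0.60), 0.30)
        assert w == pytest.approx(1.313 / 0.30, abs=1e-9)
        assert w * 0.30 == pytest.approx(1.313, abs=1e-9)
        w_up = vf.preference_weight(1.313, 0.360, (0.0, 0.30, 0.60), 0.60)
        assert w_up * 0.60 == pytest.approx(1.673, abs=1e-9)

    def test_zero_coefficients_zero_weight(self):
        for pos in (0.0, 0.1, 0.5, 0.9):
            assert vf.preference_weight(0.0, 0.0, (0.0, 0.30, 0.60), pos) == 0.0

    def test_pos_zero_returns_lower_branch_constant(self):
        assert vf.preference_weight(1.0, 0.5, (0.0, 0.25, 0.5), 0.0) == 4.0

    def test_invalid_levels_rejected(self):
        with pytest.raises(ValueError):
            vf.preference_weight(1.0, 0.5, (0.0, 0.3, 0.3), 0.5)

    def test_interpolation_identity_all_platforms(self, levels, table5):
        # w(p) * p must linearly interpolate (0,0), (b, beta_b), (c, beta_b+beta_c)
        for platform in table5.platforms:
            a, b, c = levels[platform]
            bb, bc = table5.beta_b[platform], table5.beta_c[platform]
            grid = np.linspace(0.0, c, 41)
            got = vf.preference_weight(bb, bc, (a, b, c), grid) * grid
            expected = np.interp(grid, [0.0, b, c], [0.0, bb, bb + bc])
            assert np.allclose(got, expected, atol=1e-12)


def _simulate(levels, truth, participants, seed):
    config = vf.SyntheticConfig(seed=seed, dce=vf.DCEConfig(participants=participants))
    design = vf.build_design(levels, rng=substream(seed, "design"))
    return design, vf.generate_choice_responses(config, design, truth)


class TestConditionalLogit:
    def test_recovery_of_data_generating_coefficients(self, levels, table5):
        _, data = _simulate(levels, table5, 1500, seed=31)
        fit = vf.fit_conditional_logit(data, levels)
        assert np.abs(fit.coef_vector - table5.coef_vector).max() < 0.15
        assert fit.diagnostics["converged"] == 1.0
        assert np.all(fit.se_vector > 0)

    def test_null_truth_estimates_near_zero(self, levels, table5):
        null = vf.PartWorths(
            platforms=table5.platforms,
            beta_b={p: 0.0 for p in table5.platforms},
            se_b={p: 0.0 for p in table5.platforms},
            beta_c={p: 0.0 for p in table5.platforms},
            se_c={p: 0.0 for p in table5.platforms},
        )
        within = []
        for seed in (320, 321, 322, 323, 324):
            _, data = _simulate(levels, null, 800, seed=seed)
            fit = vf.fit_conditional_logit(data, levels)
            within.extend(np.abs(fit.coef_vector) < 2 * fit.se_vector)
        assert np.mean(within) >= 0.9

    def test_matches_independent_grid_search_oracle(self):
        # one platform, 2-alternative sets: 2 coefficients, small enough for
        # an iterated grid-search oracle
        levels = vf.AttributeLevels({"RNA": (0.0, 0.3, 0.6)})
        rng = np.random.default_rng(8)
        rows = []
        lv = np.array([0.0, 0.3, 0.6])
        truth = np.array([0.9, 0.4])
        for s in range(60):
            pair = lv[rng.integers(0, 3, 2)]
            while pair[0] == pair[1]:
                pair = lv[rng.integers(0, 3, 2)]
            x = np.column_stack([(pair >= 0.3), (pair >= 0.6)]).astype(float)
            eta = x @ truth
            p = np.exp(eta) / np.exp(eta).sum()
            choice = rng.choice(2, p=p)
            for j in range(2):
                rows.append(
                    dict(participant_id="S1", block=1, set_id=f"B1S{s:02d}",
                         alternative_id=j + 1, level_rna=pair[j],
                         chosen=int(j == choice))
                )
        data = vf.ChoiceData(pd.DataFrame(rows), ("RNA",))
        fit = vf.fit_conditional_logit(data, levels)

        frame = data.frame.sort_values(["set_id", "alternative_id"])
        X = np.column_stack(
            [(frame["level_rna"] >= 0.3), (frame["level_rna"] >= 0.6)]
        ).astype(float)
        chosen = frame["chosen"].to_numpy().reshape(-1, 2).argmax(axis=1)

        def negll_grid(g0, g1):
            # log-likelihood surface over the full (bb, bc) grid at once
            grid = np.array([[a, b] for a in g0 for b in g1])  # (G, 2)
            eta = (X @ grid.T).reshape(-1, 2, grid.shape[0])  # (sets, 2, G)
            m = eta.max(axis=1, keepdims=True)
            logz = m[:, 0, :] + np.log(np.exp(eta - m).sum(axis=1))
            ll = (eta[np.arange(len(chosen)), chosen, :] - logz).sum(axis=0)
            return (-ll).reshape(len(g0), len(g1))

        lo = np.array([-4.0, -4.0])
        hi = np.array([4.0, 4.0])
        best = None
        for _ in range(5):
            g0 = np.linspace(lo[0], hi[0], 41)
            g1 = np.linspace(lo[1], hi[1], 41)
            vals = negll_grid(g0, g1)
            i, j = np.unravel_index(vals.argmin(), vals.shape)
            best = np.array([g0[i], g1[j]])
            step = np.array([g0[1] - g0[0], g1[1] - g1[0]])
            lo, hi = best - 2 * step, best + 2 * step
        assert np.abs(fit.coef_vector - best).max() < 1e-4

    def test_agrees_with_statsmodels_oracle(self, levels, table5):
        statsmodels = pytest.importorskip("statsmodels.api")
        from statsmodels.discrete.conditional_models import ConditionalLogit

        _, data = _simulate(levels, table5, 400, seed=33)
        fit = vf.fit_conditional_logit(data, levels)
        frame = data.frame.sort_values(["participant_id", "set_id", "alternative_id"])
        lv = frame[[f"level_{slug(p)}" for p in data.platforms]].to_numpy()
        X = design_matrix(lv, data.platforms, levels)
        groups = (frame["participant_id"].astype(str) + "|" + frame["set_id"]).to_numpy()
        sm_fit = ConditionalLogit(frame["chosen"].to_numpy(), X, groups=groups).fit(
            method="newton", disp=0
        )
        assert np.abs(fit.coef_vector - sm_fit.params).max() < 1e-5
        assert np.abs(fit.se_vector - sm_fit.bse).max() < 1e-4

    def test_restart_invariance(self, levels, table5):
        # concave likelihood: five random starting points, one optimum
        _, data = _simulate(levels, table5, 300, seed=34)
        rng = np.random.default_rng(0)
        fits = [
            vf.fit_conditional_logit(data, levels, start=rng.normal(0, 1, 10)).coef_vector
            for _ in range(5)
        ]
        for f in fits[1:]:
            assert np.abs(f - fits[0]).max() < 1e-6

    def test_rank_deficient_coding_named(self, levels, table5):
        _, data = _simulate(levels, table5, 50, seed=35)
        frame = data.frame.copy()
        frame["level_mab"] = 0.0  # mAb never varies -> its columns are dead
        broken = vf.ChoiceData(frame, data.platforms)
        with pytest.raises(ValueError, match="mAb"):
            vf.fit_conditional_logit(broken, levels)

    def test_separation_detected(self):
        # deterministic choices perfectly aligned with one regressor
        levels = vf.AttributeLevels({"RNA": (0.0, 0.3, 0.6)})
        rows = []
        rng = np.random.default_rng(3)
        lv = np.array([0.0, 0.3, 0.6])
        for s in range(40):
            pair = lv[rng.choice(3, 2, replace=False)]
            best = int(np.argmax(pair))
            for j in range(2):
                rows.append(
                    dict(participant_id="S1", block=1, set_id=f"B1S{s:02d}",
                         alternative_id=j + 1, level_rna=pair[j],
                         chosen=int(j == best))
                )
        data = vf.ChoiceData(pd.DataFrame(rows), ("RNA",))
        with pytest.raises(SeparationError):
            vf.fit_conditional_logit(data, levels)


class TestValidityChecks:
    def _probe_design(self, levels):
        platforms = levels.platforms
        top = np.array([[levels[p][2] for p in platforms],
                        [levels[p][0] for p in platforms],
                        [levels[p][0] for p in platforms]])
        mixed = np.array([[levels[p][1] for p in platforms],
                          [levels[p][2] if i % 2 else levels[p][0] for i, p in enumerate(platforms)],
                          [levels[p][0] if i % 2 else levels[p][2] for i, p in enumerate(platforms)]])
        # set 0 has a dominant alternative; sets 1 and 2 are identical repeats
        return vf.ChoiceDesign(levels=levels, platforms=platforms,
                               sets=((top, mixed, mixed.copy()),))

    def _answers(self, levels, design, picks):
        rows = []
        for s, pick in enumerate(picks):
            mat = design.sets[0][s]
            for j in range(mat.shape[0]):
                row = dict(participant_id="S1", block=1,
                           set_id=design.set_id(0, s), alternative_id=j + 1,
                           chosen=int(j + 1 == pick))
                for kk, p in enumerate(design.platforms):
                    row[f"level_{slug(p)}"] = mat[j, kk]
                rows.append(row)
        return vf.ChoiceData(pd.DataFrame(rows), design.platforms)

    def test_dominance_and_consistency_pass(self, levels):
        design = self._probe_design(levels)
        report = vf.validity_checks(self._answers(levels, design, [1, 2, 2]), design)
        assert report.dominance_applicable and report.consistency_applicable
        assert report.dominance_pass_rate == 1.0
        assert report.consistency_pass_rate == 1.0

    def test_inconsistent_repeat_recorded(self, levels):
        design = self._probe_design(levels)
        report = vf.validity_checks(self._answers(levels, design, [2, 2, 3]), design)
        assert report.dominance_pass_rate == 0.0
        assert report.consistency_pass_rate == 0.0

    def test_not_applicable_without_probes(self, levels):
        platforms = levels.platforms
        mixed = np.array([[levels[p][1] for p in platforms],
                          [levels[p][2] if i % 2 else levels[p][0] for i, p in enumerate(platforms)],
                          [levels[p][0] if i % 2 else levels[p][2] for i, p in enumerate(platforms)]])
        design = vf.ChoiceDesign(levels=levels, platforms=platforms, sets=((mixed,),))
        report = vf.validity_checks(self._answers(levels, design, [1]), design)
        assert not report.dominance_applicable
        assert not report.consistency_applicable
        assert report.dominance_pass_rate is None

    def test_strong_preferences_pass_dominance(self, levels, table5):
        design = self._probe_design(levels)
        config = vf.SyntheticConfig(
            seed=41, dce=vf.DCEConfig(participants=200, blocks=1, sets_per_block=3)
        )
        strong = vf.PartWorths(
            platforms=table5.platforms,
            beta_b={p: 4.0 for p in table5.platforms},
            se_b={p: 0.0 for p in table5.platforms},
            beta_c={p: 4.0 for p in table5.platforms},
            se_c={p: 0.0 for p in table5.platforms},
        )
        data = vf.generate_choice_responses(config, design, strong)
        report = vf.validity_checks(data, design)
        assert report.dominance_applicable
        assert report.dominance_pass_rate > 0.9


class TestPartWorthSampling:
    def test_zero_se_returns_point_estimates(self, table5):
        fixed = vf.PartWorths(
            platforms=table5.platforms,
            beta_b=table5.beta_b, beta_c=table5.beta_c,
            se_b={p: 0.0 for p in table5.platforms},
            se_c={p: 0.0 for p in table5.platforms},
        )
        draws = vf.sample_part_worths(fixed, 100, np.random.default_rng(0))
        for p in table5.platforms:
            assert np.all(draws.beta_b[p] == table5.beta_b[p])

    def test_mean_and_quantiles_match_normal(self, table5):
        draws = vf.sample_part_worths(table5, 100_000, np.random.default_rng(1))
        rna = draws.beta_b["RNA"]
        assert abs(rna.mean() - 1.313) < 0.002
        lo, hi = np.quantile(rna, [0.025, 0.975])
        assert lo == pytest.approx(1.313 - 1.96 * 0.081, abs=0.005)
        assert hi == pytest.approx(1.313 + 1.96 * 0.081, abs=0.005)

    def test_missing_se_rejected(self, table5):
        broken = vf.PartWorths(
            platforms=table5.platforms,
            beta_b=table5.beta_b, beta_c=table5.beta_c,
            se_b={p: np.nan for p in table5.platforms},
            se_c={p: 0.1 for p in table5.platforms},
        )
        with pytest.raises(ValueError, match="standard error"):
            vf.sample_part_worths(broken, 10, np.random.default_rng(0))


class TestPublishedFixture:
    def test_dimensions_and_values(self, table5):
        assert len(table5.coef_vector) == 10
        assert table5.beta_b["RNA"] == 1.313
        assert table5.beta_c["mAb"] == -0.043
        assert table5.se_b["Viral Vector"] == 0.082

    def test_json_round_trip(self, table5, tmp_path):
        path = tmp_path / "pw.json"
        table5.to_json(path)
        loaded = vf.PartWorths.from_json(path)
        assert np.array_equal(loaded.coef_vector, table5.coef_vector)
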