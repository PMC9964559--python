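import shutil
import subprocess

import numpy as np
import pandas as pd
import pytest
from scipy.stats import ttest_ind

from fluxprog.prognostic_modules import (
    ReactionPrognosis,
    differential_flux,
    extract_modules,
    find_prognostic_reactions,
    wda_scores,
)
from fluxprog.survival_stats import SurvivalRecord


def _surv_from_hazard(rng, log_hazard, base_rate=0.05, c_max=60.0):
    n = len(log_hazard)
    t = rng.exponential(1.0 / (base_rate * np.exp(log_hazard)))
    c = rng.uniform(0, c_max, n)
    obs = np.maximum(np.minimum(t, c), 1e-3)
    ev = (t <= c).astype(int)
    return [SurvivalRecord(f"s{i}", float(obs[i]), int(ev[i])) for i in range(n)]


class TestFindPrognostic:
    def test_planted_reaction_recovered(self):
        rng = np.random.default_rng(0)
        n = 150
        z = rng.standard_normal(n)
        flux = pd.DataFrame(
            {f"s{i}": [z[i] + 10, rng.normal(5, 1)] for i in range(n)},
            index=["planted", "noise"],
        )
        surv = _surv_from_hazard(rng, 0.9 * z)
        found = find_prognostic_reactions(flux, surv, alpha=0.01)
        ids = {p.reaction_id for p in found}
        assert "planted" in ids

    def test_direction_sign(self):
        rng = np.random.default_rng(1)
        n = 200
        z = rng.standard_normal(n)
        flux = pd.DataFrame([z + 10, -z + 10], index=["harmful", "protective"],
                            columns=[f"s{i}" for i in range(n)])
        surv = _surv_from_hazard(rng, 1.0 * z)
        found = {p.reaction_id: p for p in find_prognostic_reactions(flux, surv)}
        assert found["harmful"].direction == -1
        assert found["protective"].direction == 1

    def test_alpha_zero_empty(self):
        rng = np.random.default_rng(2)
        flux = pd.DataFrame(rng.normal(5, 1, (3, 40)),
                            index=list("abc"), columns=[f"s{i}" for i in range(40)])
        surv = _surv_from_hazard(rng, np.zeros(40))
        assert find_prognostic_reactions(flux, surv, alpha=0.0) == []

    def test_constant_reactions_skipped(self):
        rng = np.random.default_rng(3)
        flux = pd.DataFrame(
            np.vstack([np.full(40, 7.0), rng.normal(5, 1, 40)]),
            index=["const", "varying"], columns=[f"s{i}" for i in range(40)],
        )
        surv = _surv_from_hazard(rng, np.zeros(40))
        found = find_prognostic_reactions(flux, surv, alpha=1.0)
        assert all(p.reaction_id != "const" for p in found)


def _block_flux(rng, n_samples=100, rho_strength=1.0):
    """Two 3-reaction blocks driven by separate latents + one isolated."""
    z1, z2 = rng.standard_normal((2, n_samples))
    rows = {}
    for k in range(3):
        rows[f"a{k}"] = rho_strength * z1 + 0.1 * rng.standard_normal(n_samples)
    for k in range(3):
        rows[f"b{k}"] = rho_strength * z2 + 0.1 * rng.standard_normal(n_samples)
    rows["iso"] = rng.standard_normal(n_samples)
    return pd.DataFrame(rows, index=[f"s{i}" for i in range(n_samples)]).T


class TestExtractModules:
    def _prog(self, ids):
        return [ReactionPrognosis(r, 0.005, 1, -0.5) for r in ids]

    def test_triple_plus_singleton(self, rng):
        flux = _block_flux(rng)
        prog = self._prog(["a0", "a1", "a2", "iso"])
        mods = extract_modules(flux, prog, r_threshold=0.8)
        assert len(mods) == 1
        assert mods[0].members == ["a0", "a1", "a2"]

    def test_two_blocks_two_modules(self, rng):
        flux = _block_flux(rng)
        prog = self._prog(["a0", "a1", "a2", "b0", "b1", "b2"])
        mods = extract_modules(flux, prog, r_threshold=0.8)
        assert len(mods) == 2
        assert {tuple(m.members) for m in mods} == {("a0", "a1", "a2"), ("b0", "b1", "b2")}

    def test_threshold_one_only_exact_monotone_duplicates(self, rng):
        flux = _block_flux(rng)
        flux.loc["a1"] = 2 * flux.loc["a0"] + 1  # strictly monotone duplicate
        prog = self._prog(["a0", "a1", "a2", "b0"])
        mods = extract_modules(flux, prog, r_threshold=0.999999)
        assert len(mods) == 1
        assert mods[0].members == ["a0", "a1"]

    def test_order_invariance(self, rng):
        flux = _block_flux(rng)
        prog = self._prog(["a0", "a1", "a2", "b0", "b1", "b2"])
        mods1 = extract_modules(flux, prog)
        shuffled = flux.iloc[::-1, ::-1]
        mods2 = extract_modules(shuffled, list(reversed(prog)))
        assert {tuple(m.members) for m in mods1} == {tuple(m.members) for m in mods2}

    def test_min_neighbors_two_is_stricter(self, rng):
        flux = _block_flux(rng)
        flux.loc["a2"] = rng.standard_normal(flux.shape[1])  # break a2 away
        prog = self._prog(["a0", "a1", "a2"])
        loose = extract_modules(flux, prog, min_neighbors=1)
        strict = extract_modules(flux, prog, min_neighbors=2)
        assert loose and loose[0].members == ["a0", "a1"]
        assert strict == []

    def test_mixed_direction_flagged(self, rng):
        flux = _block_flux(rng)
        prog = [
            ReactionPrognosis("a0", 0.005, 1, -0.5),
            ReactionPrognosis("a1", 0.004, -1, 0.5),
            ReactionPrognosis("a2", 0.003, 1, -0.5),
        ]
        mods = extract_modules(flux, prog)
        assert mods[0].mixed_direction
        assert mods[0].direction == 1  # majority

    def test_representative_is_min_p(self, rng):
        flux = _block_flux(rng)
        prog = [
            ReactionPrognosis("a0", 0.003, 1, -0.5),
            ReactionPrognosis("a1", 0.0008, 1, -0.5),
            ReactionPrognosis("a2", 0.006, 1, -0.5),
        ]
        mods = extract_modules(flux, prog)
        assert mods[0].representative == "a1"


class TestDifferentialFlux:
    def _groups(self, n0, n1):
        return {f"s{i}": ("low" if i < n0 else "high") for i in range(n0 + n1)}

    def test_noiseless_contrast(self):
        # group means differ by exactly 1 on the log2 scale
        low = np.full(5, 4.0)
        high = np.full(5, 8.0)
        flux = pd.DataFrame(
            [np.concatenate([low, high]) * (1 + 1e-9 * np.arange(10))],
            index=["r"], columns=[f"s{i}" for i in range(10)],
        )
        out = differential_flux(flux, self._groups(5, 5), prior_df=0.0)
        assert out.loc["r", "log2fc"] == pytest.approx(1.0, abs=1e-6)

    def test_prior_df_zero_is_ordinary_t(self, rng):
        flux = pd.DataFrame(
            np.abs(rng.normal(10, 2, (50, 12))) + 0.1,
            index=[f"r{i}" for i in range(50)],
            columns=[f"s{i}" for i in range(12)],
        )
        out = differential_flux(flux, self._groups(6, 6), prior_df=0.0)
        y = np.log2(flux.to_numpy())
        t_ref = ttest_ind(y[:, 6:], y[:, :6], axis=1).statistic
        np.testing.assert_allclose(out["t_moderated"].to_numpy(), t_ref, atol=1e-12)

    def test_sign_mixed_reactions_flagged_raw(self, rng):
        flux = pd.DataFrame(
            np.vstack([rng.normal(0, 1, 12), np.abs(rng.normal(5, 1, 12))]),
            index=["mixed", "positive"], columns=[f"s{i}" for i in range(12)],
        )
        out = differential_flux(flux, self._groups(6, 6))
        assert out.loc["mixed", "scale"] == "raw"
        assert out.loc["positive", "scale"] == "log2"

    def test_null_calibration(self, rng):
        fracs = []
        for _ in range(10):
            flux = pd.DataFrame(
                np.abs(rng.normal(10, 2, (200, 20))) + 0.1,
                index=[f"r{i}" for i in range(200)],
                columns=[f"s{i}" for i in range(20)],
            )
            out = differential_flux(flux, self._groups(10, 10))
            fracs.append(out["significant"].mean())
        assert abs(np.mean(fracs) - 0.01) < 0.015

    def test_shrinkage_direction(self, rng):
        # with finite prior df, small-variance reactions are pulled toward
        # the prior (|t| shrinks) and large-variance ones away (|t| grows)
        flux = pd.DataFrame(
            np.abs(rng.normal(10, 2, (100, 12))) + 0.1,
            index=[f"r{i}" for i in range(100)],
            columns=[f"s{i}" for i in range(12)],
        )
        mod = differential_flux(flux, self._groups(6, 6))
        ord_ = differential_flux(flux, self._groups(6, 6), prior_df=0.0)
        d0 = mod["prior_df"].iloc[0]
        if not np.isfinite(d0) or d0 <= 0:
            pytest.skip("no finite prior fitted on this draw")
        y = np.log2(flux.to_numpy())
        s2 = (y[:, :6].var(axis=1, ddof=1) * 5 + y[:, 6:].var(axis=1, ddof=1) * 5) / 10
        t_mod = np.abs(mod["t_moderated"].to_numpy())
        t_ord = np.abs(ord_["t_moderated"].to_numpy())
        order = np.argsort(s2)
        assert t_mod[order[0]] <= t_ord[order[0]] + 1e-9
        assert t_mod[order[-1]] >= t_ord[order[-1]] - 1e-9

    @pytest.mark.skipif(shutil.which("Rscript") is None, reason="R not available")
    def test_against_limma_oracle(self, rng, tmp_path):
        n_rxn, n0, n1 = 80, 6, 6
        base = np.abs(rng.normal(10, 2, (n_rxn, n0 + n1))) + 0.5
        scale = rng.chisquare(4, n_rxn)[:, None] / 4.0
        y = base * np.exp(rng.standard_normal((n_rxn, n0 + n1)) * 0.2 * np.sqrt(scale))
        flux = pd.DataFrame(y, index=[f"r{i}" for i in range(n_rxn)],
                            columns=[f"s{i}" for i in range(n0 + n1)])
        out = differential_flux(flux, self._groups(n0, n1))

        mat = tmp_path / "y.tsv"
        pd.DataFrame(np.log2(y)).to_csv(mat, sep="\t", index=False, header=False)
        script = tmp_path / "limma.R"
        script.write_text(
            f"""suppressMessages(library(limma))
y <- as.matrix(read.table("{mat}", sep="\\t"))
design <- cbind(intercept=1, grp=rep(c(0,1), each={n0}))
fit <- eBayes(lmFit(y, design))
cat(fit$df.prior, fit$s2.prior, "\\n")
write.table(cbind(fit$t[,2], fit$p.value[,2]), "{tmp_path}/limma_out.tsv",
            sep="\\t", row.names=FALSE, col.names=FALSE)
"""
        )
        res = subprocess.run(["Rscript", str(script)], capture_output=True, text=True)
        assert res.returncode == 0, res.stderr
        d0_r, s20_r = map(float, res.stdout.split())
        ref = np.loadtxt(tmp_path / "limma_out.tsv")
        d0_ours = out["prior_df"].iloc[0]
        assert d0_ours == pytest.approx(d0_r, rel=0.05)
        np.testing.assert_allclose(out["t_moderated"].to_numpy(), ref[:, 0], rtol=5e-3)
        np.testing.assert_allclose(out["p_value"].to_numpy(), ref[:, 1], rtol=2e-2, atol=1e-8)


class TestWda:
    def _diff(self, rows):
        df = pd.DataFrame(rows, columns=["reaction_id", "log2fc", "significant"])
        df["t_moderated"] = 0.0
        df["p_value"] = np.where(df["significant"], 0.001, 0.5)
        return df.set_index("reaction_id")

    def test_maximal_case(self):
        # 10 fluxes, all significantly increased, only significant ones
        rows = [(f"p{i}", 1.0, True) for i in range(10)]
        rows += [(f"q{i}", 0.5, False) for i in range(5)]
        submap = {f"p{i}": "P" for i in range(10)}
        submap.update({f"q{i}": "Q" for i in range(5)})
        out = wda_scores(self._diff(rows), submap)
        assert out.loc["P", "weight"] == pytest.approx(1.0)
        assert out.loc["P", "wda"] == pytest.approx(100.0)
        assert out.loc["Q", "wda"] == 0.0

    def test_worked_arithmetic(self):
        # pathway of 20 fluxes, 6 up / 2 down significant, 40 significant
        # network-wide: Weight = 8/40 = 0.2, WDA = 100*0.2*(6-2)/20 = 4
        rows = [(f"p{i}", 1.0, True) for i in range(6)]
        rows += [(f"p{i+6}", -1.0, True) for i in range(2)]
        rows += [(f"p{i+8}", 0.1, False) for i in range(12)]
        rows += [(f"q{i}", 1.0, True) for i in range(32)]
        submap = {f"p{i}": "P" for i in range(20)}
        submap.update({f"q{i}": "Q" for i in range(32)})
        out = wda_scores(self._diff(rows), submap)
        assert out.loc["P", "weight"] == pytest.approx(0.2)
        assert out.loc["P", "wda"] == pytest.approx(4.0)

    def test_no_significant_means_zero(self):
        rows = [(f"p{i}", 1.0, False) for i in range(5)]
        out = wda_scores(self._diff(rows), {f"p{i}": "P" for i in range(5)})
        assert out.loc["P", "wda"] == 0.0

    def test_weights_sum_to_one(self, rng):
        rows = []
        submap = {}
        for p in range(4):
            for i in range(10):
                rid = f"r{p}_{i}"
                rows.append((rid, float(rng.normal()), bool(rng.random() < 0.3)))
                submap[rid] = f"path{p}"
        diff = self._diff(rows)
        if diff["significant"].sum() == 0:
            pytest.skip("no significant draws")
        out = wda_scores(diff, submap)
        assert out["weight"].sum() == pytest.approx(1.0)

    def test_wda_sign_and_bound(self, rng):
        rows = []
        submap = {}
        for p in range(3):
            for i in range(8):
                rid = f"r{p}_{i}"
                rows.append((rid, float(rng.normal()), bool(rng.random() < 0.4)))
                submap[rid] = f"path{p}"
        diff = self._diff(rows)
        total = diff["significant"].sum()
        if total == 0:
            pytest.skip("no significant draws")
        out = wda_scores(diff, submap)
        for subsystem, row in out.iterrows():
            assert np.sign(row["wda"]) == np.sign(row["n_increased"] - row["n_decreased"])
            k = row["n_increased"] + row["n_decreased"]
            bound = 100.0 * k**2 / (total * row["n_fluxes"]) + 1e-9
            assert abs(row["wda"]) <= bound
            assert abs(row["wda"]) <= 100.0 + 1e-9

    def test_missing_subsystem_excluded(self):
        rows = [("known", 1.0, True), ("orphan", 1.0, True)]
        out = wda_scores(self._diff(rows), {"known": "P"})
        assert out.loc["P", "weight"] == pytest.approx(1.0)  # orphan excluded
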