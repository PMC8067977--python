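"""Mixed-effects eigengene association, selection, connectivity, hubs."""

import subprocess
import textwrap

import numpy as np
import pandas as pd
import pytest

from conftest import bh_oracle
from tec_coexnet.association import (
    RandomInterceptModel,
    annotate_druggability,
    compare_eigengene_groups,
    fit_eigengene_model,
    intramodular_connectivity,
    select_modules,
)
from tec_coexnet.coexnet import ModuleAssignment
from tec_coexnet.simulate import SimulationConfig, simulate_cohort


@pytest.fixture(scope="module")
def cohort():
    cfg = SimulationConfig(seed=5)
    ann = simulate_cohort(cfg)
    origin = (ann["origin"] == "tumour").to_numpy(float)
    act = (ann["activation"] == "ENG+").to_numpy(float)
    return ann, origin, act


class TestMixedModel:
    def test_noiseless_fixed_effects_exact(self, cohort):
        ann, origin, act = cohort
        E = pd.DataFrame([2.0 * origin], index=["M1"], columns=ann["sample_id"])
        res = fit_eigengene_model(E, ann)
        assert res.table.loc["M1", "beta1"] == pytest.approx(2.0, abs=1e-8)
        assert res.table.loc["M1", "beta2"] == pytest.approx(0.0, abs=1e-8)

    def test_planted_effect_covered_by_three_se(self, cohort):
        ann, origin, act = cohort
        codes = pd.factorize(ann["subject_id"])[0]
        covered = 0
        n_seeds = 60
        for seed in range(n_seeds):
            rng = np.random.default_rng(seed)
            y = (
                1.0 * origin
                + rng.normal(0, 0.5, codes.max() + 1)[codes]
                + rng.normal(0, 0.5, len(ann))
            )
            m = RandomInterceptModel(y, np.column_stack([np.ones(len(ann)), origin, act]),
                                     ann["subject_id"].to_numpy())
            est, t, df, p = m.test_contrast([0, 1, 0])
            se = est / t
            covered += abs(est - 1.0) <= 3 * abs(se)
        assert covered / n_seeds >= 0.95

    def test_origin_only_module_has_dominant_t1(self, cohort):
        ann, origin, act = cohort
        codes = pd.factorize(ann["subject_id"])[0]
        wins = 0
        n_seeds = 50
        for seed in range(n_seeds):
            rng = np.random.default_rng(seed)
            y = origin + rng.normal(0, 0.5, codes.max() + 1)[codes] + rng.normal(0, 0.5, len(ann))
            m = RandomInterceptModel(y, np.column_stack([np.ones(len(ann)), origin, act]),
                                     ann["subject_id"].to_numpy())
            _, t1, _, _ = m.test_contrast([0, 1, 0])
            _, t2, _, _ = m.test_contrast([0, 0, 1])
            wins += abs(t1) > abs(t2)
        assert wins / n_seeds >= 0.95

    def test_matches_lmertest_oracle(self, cohort, tmp_path):
        """t, Satterthwaite df and p against lme4/lmerTest on one fixture."""
        ann, origin, act = cohort
        rng = np.random.default_rng(123)
        codes = pd.factorize(ann["subject_id"])[0]
        y = 0.8 * origin + 0.3 * act + rng.normal(0, 0.6, codes.max() + 1)[codes] + rng.normal(
            0, 0.7, len(ann)
        )
        m = RandomInterceptModel(y, np.column_stack([np.ones(len(ann)), origin, act]),
                                 ann["subject_id"].to_numpy())
        df = pd.DataFrame({"y": y, "origin": origin, "act": act, "subj": ann["subject_id"]})
        data_path, out_path = tmp_path / "d.tsv", tmp_path / "r.tsv"
        df.to_csv(data_path, sep="\t", index=False)
        script = textwrap.dedent(f"""
            suppressMessages(library(lmerTest))
            d <- read.delim("{data_path}")
            f <- lmer(y ~ origin + act + (1|subj), data=d)
            co <- summary(f)$coefficients
            write.table(data.frame(term=rownames(co), est=co[,1], df=co[,3],
                                   t=co[,4], p=co[,5]),
                        "{out_path}", sep="\\t", quote=FALSE, row.names=FALSE)
        """)
        subprocess.run(["Rscript", "-e", script], check=True, capture_output=True)
        r = pd.read_csv(out_path, sep="\t").set_index("term")
        for term, c in (("origin", [0, 1, 0]), ("act", [0, 0, 1])):
            est, t, dof, p = m.test_contrast(c)
            assert est == pytest.approx(r.loc[term, "est"], abs=1e-6)
            assert t == pytest.approx(r.loc[term, "t"], abs=1e-4)
            assert dof == pytest.approx(r.loc[term, "df"], abs=1e-2)
            assert p == pytest.approx(r.loc[term, "p"], abs=1e-5)


class TestSelection:
    def _assignment(self, sizes):
        labels = {}
        for i, (m, n) in enumerate(sizes.items()):
            for j in range(n):
                labels[f"{m}_g{j}"] = m
        return ModuleAssignment(pd.Series(labels))

    def test_perfect_module_selected(self):
        assignment = self._assignment({"M1": 3})
        kme = pd.DataFrame({"M1": [1.0, 1.0, 1.0]}, index=assignment.module_of_gene.index)
        sel = select_modules(kme, assignment)
        assert bool(sel.loc["M1", "selected"])

    def test_boundary_median_not_selected(self):
        assignment = self._assignment({"M1": 3})
        kme = pd.DataFrame({"M1": [0.8, 0.8, 0.8]}, index=assignment.module_of_gene.index)
        sel = select_modules(kme, assignment)
        assert sel.loc["M1", "median_abs_kme"] == pytest.approx(0.8)
        assert not bool(sel.loc["M1", "selected"])

    def test_median_matches_sort_oracle(self):
        rng = np.random.default_rng(6)
        assignment = self._assignment({"M1": 11, "M2": 8})
        kme = pd.DataFrame(
            rng.uniform(-1, 1, size=(19, 2)), index=assignment.module_of_gene.index,
            columns=["M1", "M2"],
        )
        sel = select_modules(kme, assignment)
        for m in ("M1", "M2"):
            genes = assignment.genes_of(m)
            vals = sorted(abs(v) for v in kme.loc[genes, m])
            n = len(vals)
            oracle = vals[n // 2] if n % 2 else 0.5 * (vals[n // 2 - 1] + vals[n // 2])
            assert sel.loc[m, "median_abs_kme"] == pytest.approx(oracle)


class TestConnectivity:
    def test_star_topology_hub(self):
        genes = [f"g{i}" for i in range(6)]
        A = pd.DataFrame(np.eye(6) * 0.0, index=genes, columns=genes)
        A.iloc[0, 1:] = A.iloc[1:, 0] = 0.9
        for i in range(1, 6):
            for j in range(1, 6):
                if i != j:
                    A.iloc[i, j] = 0.05
        np.fill_diagonal(A.values, 1.0)
        assignment = ModuleAssignment(pd.Series("M1", index=genes))
        table = intramodular_connectivity(A, assignment)
        assert table.loc["g0", "kWithin_norm"] == pytest.approx(1.0)
        assert bool(table.loc["g0", "is_hub"])

    def test_ceiling_rule_hub_count(self):
        rng = np.random.default_rng(7)
        genes = [f"g{i:02d}" for i in range(29)]
        M = rng.uniform(0, 1, size=(29, 29))
        A = pd.DataFrame((M + M.T) / 2, index=genes, columns=genes)
        np.fill_diagonal(A.values, 1.0)
        assignment = ModuleAssignment(pd.Series("M1", index=genes))
        table = intramodular_connectivity(A, assignment)
        assert int(table["is_hub"].sum()) == 3  # ceil(2.9)

    def test_kwithin_matches_double_loop_oracle(self):
        rng = np.random.default_rng(8)
        genes = [f"g{i:02d}" for i in range(50)]
        M = rng.uniform(0, 1, size=(50, 50))
        A = pd.DataFrame((M + M.T) / 2, index=genes, columns=genes)
        np.fill_diagonal(A.values, 1.0)
        assignment = ModuleAssignment(pd.Series("M1", index=genes))
        table = intramodular_connectivity(A, assignment)
        for g in genes:
            oracle = sum(A.loc[g, h] for h in genes if h != g)
            assert table.loc[g, "kWithin"] == pytest.approx(oracle, abs=1e-12)
        # exactly one gene attains the maximum (up to ties)
        assert (table["kWithin_norm"] == 1.0).sum() >= 1
        assert table["kWithin_norm"].between(0, 1).all()

    def test_hub_ranking_invariant_to_positive_scaling(self):
        rng = np.random.default_rng(9)
        genes = [f"g{i:02d}" for i in range(20)]
        M = rng.uniform(0, 1, size=(20, 20))
        A = pd.DataFrame((M + M.T) / 2, index=genes, columns=genes)
        np.fill_diagonal(A.values, 1.0)
        assignment = ModuleAssignment(pd.Series("M1", index=genes))
        t1 = intramodular_connectivity(A, assignment)
        t2 = intramodular_connectivity(A * 0.37, assignment)
        pd.testing.assert_series_equal(t1["is_hub"], t2["is_hub"])


class TestGroupComparisons:
    def test_identical_groups_give_p_one(self):
        # four groups with byte-identical value multisets -> t = 0, p = 1
        rows = []
        values = [1.0, 2.0, 3.0, 4.0]
        for gi, (origin, activation) in enumerate(
            [("non-tumour", "ENG-"), ("non-tumour", "ENG+"), ("tumour", "ENG-"), ("tumour", "ENG+")]
        ):
            for si in range(4):
                rows.append(
                    {"sample_id": f"s{gi}{si}", "subject_id": f"P{si}",
                     "origin": origin, "activation": activation}
                )
        ann = pd.DataFrame(rows)
        E = pd.DataFrame([values * 4], index=["M1"], columns=ann["sample_id"])
        table = compare_eigengene_groups(E, ann)
        assert (table["p"] > 0.99).all()

    def test_separated_groups_detected(self, cohort):
        ann, origin, _ = cohort
        rng = np.random.default_rng(10)
        y = 10.0 * origin + rng.normal(0, 1.0, len(ann))
        E = pd.DataFrame([y], index=["M1"], columns=ann["sample_id"])
        table = compare_eigengene_groups(E, ann)
        row = table[(table.group1 == "NECneg") & (table.group2 == "TECneg")].iloc[0]
        assert row["p_adj"] < 0.001

    def test_bh_within_module_matches_oracle(self, cohort):
        ann, _, _ = cohort
        rng = np.random.default_rng(11)
        E = pd.DataFrame(rng.normal(size=(2, len(ann))), index=["M1", "M2"],
                         columns=ann["sample_id"])
        table = compare_eigengene_groups(E, ann)
        for m in ("M1", "M2"):
            sub = table[table.module == m]
            np.testing.assert_allclose(sub["p_adj"], bh_oracle(sub["p"]), atol=1e-12)


class TestDruggability:
    @staticmethod
    def _hubs():
        return pd.DataFrame(
            {"module": ["M1", "M1"], "kWithin": [3.0, 2.0], "kWithin_norm": [1.0, 0.7],
             "is_hub": [True, True]},
            index=pd.Index(["KDR", "Birc5"], name="gene_id"),
        )

    def test_empty_table_flags_nothing(self):
        drugs = pd.DataFrame(columns=["gene_id", "drug", "evidence"])
        out = annotate_druggability(self._hubs(), drugs)
        assert not out["druggable"].any()

    def test_multiple_drugs_multiple_rows(self):
        drugs = pd.DataFrame(
            {"gene_id": ["KDR", "KDR"], "drug": ["sunitinib", "sorafenib"],
             "evidence": ["a", "b"]}
        )
        out = annotate_druggability(self._hubs(), drugs)
        assert (out[out.gene_id == "KDR"].shape[0]) == 2

    def test_case_insensitive_matching(self):
        drugs = pd.DataFrame(
            {"gene_id": ["BIRC5"], "drug": ["ym155"], "evidence": ["c"]}
        )
        out = annotate_druggability(self._hubs(), drugs)
        assert bool(out.loc[out.gene_id == "Birc5", "druggable"].iloc[0])
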