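import numpy as np
import pandas as pd
import pytest

from droughtring import synth
from droughtring.kinship import FamilyAssigner, a_matrix, assign_families, vanraden_g


def ped_frame(rows):
    return pd.DataFrame(rows, columns=["id", "dam", "sire", "family"])


class TestAMatrix:
    def test_parent_offspring_half(self):
        ped = ped_frame([("D", None, None, "F"), ("O", "D", None, "F")])
        A = a_matrix(ped)
        assert A.loc["D", "O"] == 0.5
        assert A.loc["O", "O"] == 1.0

    def test_halfsibs_quarter(self):
        ped = ped_frame([
            ("D", None, None, "F"),
            ("O1", "D", None, "F"),
            ("O2", "D", None, "F"),
        ])
        A = a_matrix(ped)
        assert A.loc["O1", "O2"] == 0.25

    def test_fullsibs_and_inbreeding(self):
        ped = ped_frame([
            ("D", None, None, "F"), ("S", None, None, "F"),
            ("O1", "D", "S", "F"), ("O2", "D", "S", "F"),
            ("X", "O1", "O2", "F"),  # mating of full sibs -> F = 0.25
        ])
        A = a_matrix(ped)
        assert A.loc["O1", "O2"] == 0.5
        assert A.loc["X", "X"] == pytest.approx(1.25)

    def test_order_independent(self):
        ped = ped_frame([
            ("O2", "D", None, "F"), ("O1", "D", None, "F"), ("D", None, None, "F"),
        ])
        A = a_matrix(ped)
        assert A.loc["O1", "O2"] == 0.25

    def test_cycle_rejected(self):
        ped = ped_frame([("A", "B", None, "F"), ("B", "A", None, "F")])
        with pytest.raises(ValueError, match="cycle"):
            a_matrix(ped)

    def test_matches_gene_dropping_on_random_pedigree(self):
        """Tabular A equals Monte-Carlo gene-dropping covariances."""
        rng = np.random.default_rng(7)
        rows = [(f"F{i}", None, None, "G") for i in range(4)]
        parents = [f"F{i}" for i in range(4)]
        for g in range(6):  # two generations of random matings
            dam, sire = rng.choice(parents, 2, replace=False)
            rows.append((f"I{g}", dam, sire, "G"))
            parents.append(f"I{g}")
        ped = ped_frame(rows)
        ids = [r[0] for r in rows]
        A = a_matrix(ped).loc[ids, ids].to_numpy()
        # allele-level gene dropping: two allele values per founder, each
        # offspring inherits one random allele per parent (handles inbreeding)
        idx = {i: k for k, i in enumerate(ids)}
        R = 200_000
        al = np.zeros((len(ids), 2, R))
        for k, row in enumerate(rows):
            for slot, parent in enumerate(row[1:3]):
                p = idx.get(parent) if isinstance(parent, str) else None
                if p is None:
                    al[k, slot] = rng.normal(0.0, np.sqrt(0.5), R)
                else:
                    pick = rng.integers(0, 2, R)
                    al[k, slot] = al[p, pick, np.arange(R)]
        bv = al.sum(axis=1)
        Ahat = (bv @ bv.T) / R
        se = np.sqrt((np.outer(np.diag(A), np.diag(A)) + A**2) / R)
        assert np.all(np.abs(Ahat - A) < np.maximum(4 * se, 0.01))


class TestVanRaden:
    def test_identical_homozygotes_hand_formula(self):
        # two identical individuals, alternating homozygotes, base p = 0.5:
        # Z entries are +-1, so ZZ' = 4 and 2*sum p(1-p) = 2 -> G entries = 2
        # (fully homozygous duplicates exceed the outbred diagonal of 1)
        M = pd.DataFrame([[2, 0, 2, 0], [2, 0, 2, 0]], index=["a", "b"], dtype=float)
        G = vanraden_g(M, maf_floor=0.0, allele_freq=[0.5] * 4)
        assert G.loc["a", "b"] == pytest.approx(2.0)
        assert G.loc["a", "a"] == pytest.approx(2.0)

    def test_het_and_hom_pair_hand_formula(self):
        # identical heterozygotes at p = 0.5 have Z = 0: G entries 0
        M = pd.DataFrame([[1, 1, 1, 1], [1, 1, 1, 1]], index=["a", "b"], dtype=float)
        G = vanraden_g(M, maf_floor=0.0, allele_freq=[0.5] * 4)
        assert G.loc["a", "b"] == pytest.approx(0.0)

    def test_hwe_founders_diagonal_near_one(self):
        rng = np.random.default_rng(1)
        p = rng.uniform(0.1, 0.5, 5000)
        M = pd.DataFrame(rng.binomial(2, p, size=(40, 5000)).astype(float))
        G = vanraden_g(M)
        assert np.mean(np.diag(G)) == pytest.approx(1.0, abs=0.05)

    def test_unrelated_founders_off_diagonal_near_zero(self):
        rng = np.random.default_rng(2)
        p = rng.uniform(0.1, 0.5, 3000)
        M = pd.DataFrame(rng.binomial(2, p, size=(30, 3000)).astype(float))
        # with base-population frequencies the expectation is exactly 0
        G = vanraden_g(M, allele_freq=p).to_numpy()
        off = G[np.triu_indices(30, 1)]
        assert abs(off.mean()) < 0.02
        # sample-frequency centring shifts the mean to ~ -1/(n-1)
        Gs = vanraden_g(M).to_numpy()
        offs = Gs[np.triu_indices(30, 1)]
        assert offs.mean() == pytest.approx(-1 / 29, abs=0.02)

    def test_halfsib_mean_relationship(self, small_study):
        ped = small_study["pedigree"]
        geno = synth.simulate_snps(ped, n_snps=800, seed=21)
        off = ped[ped["dam"].notna()]
        G = vanraden_g(geno.loc[off["id"]])
        vals = []
        for fam, g in off.groupby("true_family"):
            ids = g["id"].tolist()
            sub = G.loc[ids, ids].to_numpy()
            vals.append(sub[np.triu_indices(len(ids), 1)].mean())
        assert np.mean(vals) == pytest.approx(0.25, abs=0.04)

    def test_monomorphic_panel_rejected(self):
        M = pd.DataFrame(np.full((5, 4), 2.0))
        with pytest.raises(ValueError):
            vanraden_g(M)

    def test_symmetry(self, small_study):
        geno = synth.simulate_snps(small_study["pedigree"].head(60), n_snps=100, seed=3)
        G = vanraden_g(geno)
        assert np.allclose(G, G.T)


@pytest.fixture(scope="module")
def contaminated():
    lay = synth.simulate_design(n_sites=1, n_families=40, n_sets=5, n_blocks=5, seed=30)
    lay = lay.groupby("family").head(10).reset_index(drop=True)
    ped = synth.build_op_pedigree(lay, contamination_rate=0.05, seed=31)
    geno = synth.simulate_snps(ped, n_snps=500, seed=32)
    off = ped[ped["dam"].notna()]
    G = vanraden_g(geno.loc[off["id"]])
    return ped, G


class TestFamilyAssignment:
    def test_clean_data_no_reassignment(self):
        lay = synth.simulate_design(n_sites=1, n_families=10, n_sets=2, n_blocks=5, seed=33)
        lay = lay.groupby("family").head(8).reset_index(drop=True)
        ped = synth.build_op_pedigree(lay, contamination_rate=0.0, seed=34)
        geno = synth.simulate_snps(ped, n_snps=500, seed=35)
        off = ped[ped["dam"].notna()]
        G = vanraden_g(geno.loc[off["id"]])
        _, changes = assign_families(G, ped)
        assert len(changes) == 0

    def test_mislabels_corrected(self, contaminated):
        ped, G = contaminated
        fa = FamilyAssigner().fit(G, ped)
        off = ped[ped["dam"].notna()].set_index("id")
        mislabeled = off[off["family"] != off["true_family"]]
        assert len(mislabeled) > 0
        new = fa.pedigree_.set_index("id")
        corrected = (new.loc[mislabeled.index, "family"] == mislabeled["true_family"]).mean()
        assert corrected >= 0.95

    def test_unrelated_individual_unassigned(self, contaminated):
        ped, G = contaminated
        G2 = G.copy()
        stranger = G2.index[0]
        G2.loc[stranger, :] = 0.0
        G2.loc[:, stranger] = 0.0
        G2.loc[stranger, stranger] = 1.0
        fa = FamilyAssigner().fit(G2, ped)
        row = fa.assignments_.set_index("id").loc[stranger]
        assert row["new_family"] is None

    def test_idempotent(self, contaminated):
        ped, G = contaminated
        first, changes1 = assign_families(G, ped)
        second, changes2 = assign_families(G, first)
        assert len(changes2) == 0
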