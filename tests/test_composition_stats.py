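import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from psychrocomp.composition_stats import (
    AA_ORDER,
    aa_composition,
    composition_table,
    cumulative_composition_by_gc,
    deviation_profile,
    gc_aa_correlation,
    group_compare,
    nt_content,
    welch_t,
)
from psychrocomp.genome_io import CDSRecord, GenomeCollection, GenomeMeta


class TestAaComposition:
    def test_single_residue(self):
        comp = aa_composition(["AAAA"])
        assert comp["A"] == 100.0
        assert sum(comp.values) == pytest.approx(100.0, abs=1e-9)

    def test_uniform(self):
        comp = aa_composition(["ACDEFGHIKLMNPQRSTVWY"])
        assert all(v == pytest.approx(5.0) for v in comp.values)

    def test_x_excluded_from_both_sides(self):
        comp = aa_composition(["AAX", "A"])
        assert comp["A"] == 100.0 and comp.total == 3

    def test_no_canonical_residues(self):
        with pytest.raises(ValueError):
            aa_composition(["XXX"])

    @settings(deadline=None, max_examples=30, derandomize=True)
    @given(st.lists(st.text(alphabet=AA_ORDER, min_size=1, max_size=40), min_size=2, max_size=6))
    def test_pooling_consistency(self, proteins):
        """Pooled composition equals the count-weighted mean of the parts."""
        whole = aa_composition(proteins)
        parts = [aa_composition([p]) for p in proteins]
        weights = np.array([p.total for p in parts], dtype=float)
        stacked = np.array([p.values for p in parts])
        weighted = (stacked * weights[:, None]).sum(axis=0) / weights.sum()
        assert np.allclose(whole.values, weighted, atol=1e-9)


class TestNtContent:
    @pytest.mark.parametrize(
        "seq,gc,ag,total",
        [("ATGC", 50.0, 50.0, 4), ("GGCC", 100.0, 50.0, 4), ("AANT", 0.0, 100.0 * 2 / 3, 3)],
    )
    def test_examples(self, seq, gc, ag, total):
        res = nt_content([seq])
        assert res.gc_percent == pytest.approx(gc)
        assert res.ag_percent == pytest.approx(ag)
        assert res.total == total

    def test_all_n_rejected(self):
        with pytest.raises(ValueError):
            nt_content(["NNN"])


class TestDeviationProfile:
    def test_identical_entities_zero(self):
        import pandas as pd

        t = pd.DataFrame({"A": [9.0, 9.0], "I": [5.0, 5.0]})
        assert (deviation_profile(t) == 0).all().all()

    def test_two_entity_arithmetic_and_centering(self):
        import pandas as pd

        t = pd.DataFrame({"A": [9.0, 8.0]})
        dev = deviation_profile(t)
        assert list(dev["A"]) == [0.5, -0.5]
        assert abs(dev.sum(axis=0)).max() < 1e-9

    def test_single_entity_rejected(self):
        import pandas as pd

        with pytest.raises(ValueError):
            deviation_profile(pd.DataFrame({"A": [1.0]}))


class TestWelchT:
    def test_identical_groups(self):
        delta, t, p = welch_t([1.0, 2.0, 3.0], [1.0, 2.0, 3.0])
        assert (delta, t, p) == (0.0, 0.0, 1.0)

    def test_antisymmetry(self):
        rng = np.random.default_rng(3)
        x, y = rng.normal(0, 1, 10), rng.normal(1, 2, 12)
        d1, t1, p1 = welch_t(x, y)
        d2, t2, p2 = welch_t(y, x)
        assert d1 == -d2 and t1 == pytest.approx(-t2) and p1 == pytest.approx(p2)

    def test_matches_permutation_oracle(self):
        """Welch p agrees with a label-permutation oracle at moderate effect."""
        rng = np.random.default_rng(12)
        x = rng.normal(0.0, 1.0, 25)
        y = rng.normal(0.55, 1.0, 25)
        delta, t, p = welch_t(x, y)
        pooled = np.concatenate([x, y])
        n = len(x)
        count = 0
        reps = 4000
        for _ in range(reps):
            perm = rng.permutation(pooled)
            d = perm[:n].mean() - perm[n:].mean()
            if abs(d) >= abs(delta):
                count += 1
        p_perm = count / reps
        assert abs(p - p_perm) < 0.05

    def test_small_groups_rejected(self):
        with pytest.raises(ValueError):
            welch_t([1.0], [1.0, 2.0])


def _collection_from_comp(proteins_by_genome, habitat_by_genome, nt_by_genome=None):
    metas = [
        GenomeMeta(genome_id=g, habitat=habitat_by_genome.get(g, "unlabeled"))
        for g in proteins_by_genome
    ]
    cds = []
    for g, prots in proteins_by_genome.items():
        for i, aa in enumerate(prots):
            nt = (nt_by_genome or {}).get(g, [None] * len(prots))[i]
            cds.append(
                CDSRecord(cds_id=f"{g}.c{i}", genome_id=g, aa_seq=aa, nt_seq=nt or "")
            )
    return GenomeCollection(metas=metas, cds=cds, hierarchy=[frozenset(proteins_by_genome)])


class TestGroupCompare:
    def test_duplicated_group_all_deltas_zero(self):
        prots = {g: ["M" * 40] for g in ("g1", "g2", "g3", "g4")}
        nts = {g: ["ATG" * 40 + "TAA"] for g in prots}
        habitat = {"g1": "cold", "g2": "cold", "g3": "warm", "g4": "warm"}
        col = _collection_from_comp(prots, habitat, nts)
        df = group_compare(col)
        assert (df["delta"] == 0).all()
        assert (df["p"] == 1.0).all()

    def test_missing_labels_rejected(self):
        prots = {"g1": ["MKVA"], "g2": ["MKVA"], "g3": ["MKVA"], "g4": ["MKVA"]}
        habitat = {"g1": "cold", "g2": "cold", "g3": "warm"}
        col = _collection_from_comp(prots, habitat)
        with pytest.raises(ValueError, match="missing habitat"):
            group_compare(col)

    def test_single_group_rejected(self):
        prots = {f"g{i}": ["MKVA"] for i in range(4)}
        habitat = {f"g{i}": "cold" for i in range(4)}
        col = _collection_from_comp(prots, habitat)
        with pytest.raises(ValueError, match=">= 2 genomes"):
            group_compare(col)


class TestGcAaCorrelation:
    def test_zero_gc_variance_rejected(self):
        prots = {f"g{i}": ["M" * 10] for i in range(3)}
        nts = {g: ["ATG" * 10 + "TAA"] for g in prots}
        col = _collection_from_comp(prots, {}, nts)
        with pytest.raises(ValueError, match="zero variance"):
            gc_aa_correlation(col)

    def test_two_genomes_rejected(self):
        prots = {"g1": ["M" * 4], "g2": ["M" * 4]}
        nts = {g: ["ATG" * 4 + "TAA"] for g in prots}
        col = _collection_from_comp(prots, {}, nts)
        with pytest.raises(ValueError, match=">= 3 genomes"):
            gc_aa_correlation(col)

    def test_cumulative_ordering_by_gc(self, small_collection):
        collection, _ = small_collection
        natives = collection.hierarchy[0]
        sub = GenomeCollection(
            metas=[m for m in collection.metas if m.genome_id in natives],
            cds=[c for c in collection.cds if c.genome_id in natives],
            hierarchy=list(collection.hierarchy),
        )
        cum = cumulative_composition_by_gc(sub)
        assert list(cum["GC"]) == sorted(cum["GC"])
        # last cumulative column reaches 100
        assert np.allclose(cum[AA_ORDER[-1]], 100.0, atol=1e-9)


class TestNullCalibration:
    def test_type_one_error_rate(self):
        """Under a no-shift simulation, each feature's p<0.05 rate over label
        shuffles stays near the nominal 5% level."""
        from psychrocomp.synthetic_data import SimConfig, simulate_collection

        cfg = SimConfig(
            seed=101,
            hierarchy_sizes=(20,),
            families_per_level=(60,),
            private_families=0,
            n_hgt=0,
            aa_shift={},
            cold_genomes=(),
            mean_protein_len=120,
        )
        collection, _ = simulate_collection(cfg)
        table = composition_table(collection)
        feats = table.to_numpy()  # (20 genomes, 22 features)
        rng = np.random.default_rng(202)
        n_shuffles = 1200
        n = feats.shape[0]
        half = n // 2
        # vectorized Welch t over shuffles
        rates = np.zeros(feats.shape[1])
        from scipy import stats

        hits = np.zeros(feats.shape[1])
        for _ in range(n_shuffles):
            perm = rng.permutation(n)
            x, y = feats[perm[:half]], feats[perm[half:]]
            t, p = stats.ttest_ind(x, y, equal_var=False, axis=0)
            hits += p < 0.05
        rates = hits / n_shuffles
        assert np.all(rates > 0.02) and np.all(rates < 0.09)
        assert abs(rates.mean() - 0.05) < 0.02
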