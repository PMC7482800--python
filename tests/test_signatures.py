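import numpy as np
import pytest
from hypothesis import given
from hypothesis import strategies as st

from clonemark.contexts import CONTEXT_INDEX, reverse_complement
from clonemark.signatures import (
    fit_signatures,
    smg_candidates,
    spectra_chisq,
    spectrum,
)

from conftest import make_snv


class TestSpectrum:
    def test_single_c_to_t_at_aca(self):
        prof = spectrum([make_snv(ref="C", alt="T", context="ACA")])
        assert prof.by_class() == {"C>A": 0, "C>G": 0, "C>T": 1, "T>A": 0, "T>C": 0, "T>G": 0}
        assert prof.counts96[CONTEXT_INDEX["A[C>T]A"]] == 1
        assert prof.total == 1

    def test_purine_strand_collapses(self):
        # G>A at TGT is C>T at ACA on the pyrimidine strand
        prof = spectrum([make_snv(ref="G", alt="A", context="TGT")])
        assert prof.counts96[CONTEXT_INDEX["A[C>T]A"]] == 1

    def test_sig1_mutations_have_c_to_t_mode(self, catalog):
        rng = np.random.default_rng(3)
        p = catalog.matrix["S1"].to_numpy()
        counts = rng.multinomial(300, p)
        from clonemark.signatures import SpectrumProfile

        prof = SpectrumProfile(counts)
        assert int(np.argmax(prof.counts6)) == 2  # C>T class

    def test_strand_collapse_symmetry(self):
        rng = np.random.default_rng(8)
        labels = list(CONTEXT_INDEX)
        records = []
        for i in range(200):
            lab = labels[rng.integers(96)]
            five, ref, alt, three = lab[0], lab[2], lab[4], lab[6]
            records.append(make_snv(pos=i + 1, ref=ref, alt=alt, context=five + ref + three))
        flipped = [
            make_snv(
                pos=r.pos,
                ref=reverse_complement(r.ref),
                alt=reverse_complement(r.alt),
                context=reverse_complement(r.context),
            )
            for r in records
        ]
        assert (spectrum(records).counts96 == spectrum(flipped).counts96).all()

    def test_indel_input_rejected(self):
        from conftest import make_indel

        with pytest.raises(ValueError):
            spectrum([make_indel()])


class TestChisq:
    def test_identical_profiles_statistic_zero(self):
        a = np.array([10, 10, 10, 10, 10, 10])
        stat, df, p = spectra_chisq(a, a)
        assert stat == pytest.approx(0.0)
        assert p == pytest.approx(1.0)

    def test_collapsed_2x2_closed_form(self):
        # [[10,20],[20,10]]: all expected 15, chi2 = 4*25/15 = 6.6667
        a = np.array([10, 20, 0, 0, 0, 0])
        b = np.array([20, 10, 0, 0, 0, 0])
        stat, df, p = spectra_chisq(a, b)
        assert stat == pytest.approx(6.6667, abs=1e-4)
        assert df == 1

    def test_zero_total_profile_rejected(self):
        with pytest.raises(ValueError):
            spectra_chisq(np.zeros(6), np.array([1, 0, 0, 0, 0, 0]))

    @given(st.lists(st.integers(5, 60), min_size=12, max_size=12))
    def test_matches_brute_force_pearson(self, counts):
        a = np.array(counts[:6], dtype=float)
        b = np.array(counts[6:], dtype=float)
        stat, df, p = spectra_chisq(a, b, pool_expected_below=0.0)
        table = np.vstack([a, b])
        expected = np.outer(table.sum(1), table.sum(0)) / table.sum()
        brute = ((table - expected) ** 2 / expected).sum()
        assert stat == pytest.approx(brute, abs=1e-9)


class TestFitSignatures:
    def test_pure_catalog_column_recovered_exactly(self, catalog):
        prof = catalog.matrix["S1"].to_numpy() * 500
        exp = fit_signatures(prof, catalog)
        assert exp.weights == pytest.approx({"S1": 1.0}, abs=1e-6)
        assert exp.residual < 1e-8

    def test_noise_free_two_component_mixture(self, catalog):
        m = 0.7 * catalog.matrix["S1"].to_numpy() + 0.3 * catalog.matrix["S4"].to_numpy()
        exp = fit_signatures(m, catalog)
        assert exp.weights["S1"] == pytest.approx(0.7, abs=1e-3)
        assert exp.weights["S4"] == pytest.approx(0.3, abs=1e-3)

    def test_floor_prunes_trace_weights(self, catalog):
        m = 0.97 * catalog.matrix["S1"].to_numpy() + 0.03 * catalog.matrix["S7"].to_numpy()
        exp = fit_signatures(m, catalog, weight_floor=0.06)
        assert "S7" not in exp.weights

    def test_related_regime_tumor_is_sig1_dominated(self, catalog):
        rng = np.random.default_rng(21)
        p = catalog.mixture({"S1": 0.8, "S5": 0.2})
        counts = rng.multinomial(200, p)
        exp = fit_signatures(counts.astype(float), catalog)
        assert exp.dominant() == "S1"

    def test_empty_profile_rejected(self, catalog):
        with pytest.raises(ValueError):
            fit_signatures(np.zeros(96), catalog)


class TestSmgCandidates:
    def _cohort(self):
        return {
            "P1": [make_snv(gene="TP53", patient_id="P1", sample_id="P1_T")],
            "P2": [
                make_snv(gene="TP53", patient_id="P2", sample_id="P2_D"),
                make_snv(gene="RPL5", patient_id="P2", sample_id="P2_T", pos=5),
            ],
            "P3": [make_snv(gene="MUC16", patient_id="P3", sample_id="P3_T", effect="synonymous")],
        }

    def test_single_patient_gene_excluded(self):
        out = smg_candidates(self._cohort())
        genes = [c.gene for c in out]
        assert "RPL5" not in genes and "TP53" in genes

    def test_synonymous_only_gene_excluded(self):
        out = smg_candidates(self._cohort(), min_patients=1)
        assert "MUC16" not in [c.gene for c in out]

    def test_planted_recurrent_gene_ranks_first(self):
        cohort = {
            f"P{i}": [
                make_snv(gene="TP53", patient_id=f"P{i}", sample_id=f"P{i}_T", pos=i),
                make_snv(gene=f"G{i}", patient_id=f"P{i}", sample_id=f"P{i}_T", pos=100 + i),
            ]
            for i in range(10)
        }
        cohort["P0"].append(make_snv(gene="G1", patient_id="P0", sample_id="P0_T", pos=500))
        out = smg_candidates(cohort)
        assert out[0].gene == "TP53" and out[0].n_patients_mutated == 10

    def test_cosmic_restriction(self):
        out = smg_candidates(self._cohort(), cosmic_genes={"RPL5"})
        assert out == []
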