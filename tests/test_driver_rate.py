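import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from clonaltiming.driver_rate import (
    DriverConsequenceSet,
    MutationSpectrum,
    all_classes,
    all_contexts,
    driver_substitution_rate,
    enumerate_cds_substitutions,
    indel_driver_rate,
    pyrimidine_class,
    round_sigfigs,
    spectrum_context_rates,
    total_driver_rate,
    uniform_context_counts,
)

TOY_CDS = "ATGTGGTGA"  # Met - Trp - stop


class TestClasses:
    def test_96_classes(self):
        classes = all_classes()
        assert len(classes) == 96
        assert len(set(classes)) == 96

    def test_32_contexts(self):
        assert len(all_contexts()) == 32

    def test_pyrimidine_collapse(self):
        # G-centred context collapses to the reverse complement
        assert pyrimidine_class("AGA", "T") == ("TCT", "A")
        assert pyrimidine_class("ACA", "T") == ("ACA", "T")


class TestSpectrumRates:
    def test_single_class(self):
        spectrum = MutationSpectrum(counts={"ACA>T": 10.0}, total_rate=5.0)
        rates = spectrum_context_rates(spectrum, {"ACA": 100.0})
        assert rates == {"ACA>T": pytest.approx(5.0 / 100.0)}

    def test_uniform_over_shared_context(self):
        spectrum = MutationSpectrum(counts={"ACA>T": 5.0, "ACA>G": 5.0}, total_rate=2.0)
        rates = spectrum_context_rates(spectrum, {"ACA": 50.0})
        assert rates["ACA>T"] == pytest.approx(rates["ACA>G"])

    def test_conservation_identity(self):
        rng = np.random.default_rng(0)
        counts = {cls: float(rng.integers(0, 50)) for cls in all_classes()}
        counts["ACA>T"] += 1  # ensure non-empty
        spectrum = MutationSpectrum(counts=counts, total_rate=87.0)
        sites = {ctx: float(rng.integers(10_000, 1_000_000)) for ctx in all_contexts()}
        rates = spectrum_context_rates(spectrum, sites)
        total = sum(rate * sites[cls.split(">")[0]] for cls, rate in rates.items())
        assert total == pytest.approx(87.0, rel=1e-9)

    def test_missing_context_rejected(self):
        spectrum = MutationSpectrum(counts={"ACA>T": 1.0}, total_rate=1.0)
        with pytest.raises(ValueError, match="missing"):
            spectrum_context_rates(spectrum, {"TTT": 5.0})

    def test_unknown_class_rejected(self):
        with pytest.raises(ValueError, match="unknown"):
            MutationSpectrum(counts={"AGA>T": 1.0}, total_rate=1.0)  # purine-centred


class TestEnumeration:
    def test_3l_substitutions(self):
        ann = enumerate_cds_substitutions(TOY_CDS)
        assert len(ann) == 3 * len(TOY_CDS)

    def test_toy_stop_gained(self):
        ann = enumerate_cds_substitutions(TOY_CDS)
        stop_gained = ann[ann["consequence"] == "stop_gained"]
        # TGG -> TAG and TGG -> TGA
        assert len(stop_gained) == 2

    def test_toy_start_lost(self):
        ann = enumerate_cds_substitutions(TOY_CDS)
        codon1 = ann[ann["codon_index"] == 0]
        assert (codon1["consequence"] == "start_lost").all()
        assert len(codon1) == 9

    def test_internal_stop_rejected(self):
        with pytest.raises(ValueError, match="internal stop"):
            enumerate_cds_substitutions("ATGTAATGGTGA")

    @pytest.mark.parametrize("bad", ["ATGTG", "TTGTGGTGA", "ATGTGGAAA"])
    def test_malformed_cds_rejected(self, bad):
        with pytest.raises(ValueError):
            enumerate_cds_substitutions(bad)

    @given(n_codons=st.integers(0, 12), data=st.data())
    @settings(max_examples=30, deadline=None)
    def test_consequence_counts_sum_to_3l(self, n_codons, data):
        # random internal codons avoiding stops
        from clonaltiming.driver_rate import STOP_CODONS, BASES

        codons = ["ATG"]
        for _ in range(n_codons):
            while True:
                codon = "".join(data.draw(st.sampled_from(BASES)) for _ in range(3))
                if codon not in STOP_CODONS:
                    break
            codons.append(codon)
        codons.append(data.draw(st.sampled_from(sorted(STOP_CODONS))))
        cds = "".join(codons)
        ann = enumerate_cds_substitutions(cds)
        assert len(ann) == 3 * len(cds)
        assert ann["consequence"].value_counts().sum() == 3 * len(cds)

    def test_brute_force_translation_oracle(self):
        # independently recompute every consequence by codon translation
        from Bio.Seq import Seq

        cds = "ATGGCTTGGCGATTAGACTAA"
        ann = enumerate_cds_substitutions(cds)
        protein = str(Seq(cds).translate())
        for row in ann.itertuples(index=False):
            mutated = cds[: row.pos] + row.alt + cds[row.pos + 1 :]
            mut_protein = str(Seq(mutated).translate())
            if row.codon_index == 0:
                expected = "start_lost" if mutated[:3] != "ATG" else "synonymous"
            elif protein[row.codon_index] == "*":
                expected = "synonymous" if mut_protein[row.codon_index] == "*" else "stop_lost"
            elif mut_protein[row.codon_index] == "*":
                expected = "stop_gained"
            elif mut_protein[row.codon_index] == protein[row.codon_index]:
                expected = "synonymous"
            else:
                expected = "missense"
            assert row.consequence == expected


class TestDriverRate:
    def test_single_driver_site(self):
        ann = enumerate_cds_substitutions(TOY_CDS)
        drivers = DriverConsequenceSet(start_lost=False, stop_lost=False, stop_gained=True)
        stop_class = ann.loc[ann["consequence"] == "stop_gained", "mut_class"].iloc[0]
        rates = {stop_class: 1e-7}
        assert driver_substitution_rate(ann.head(0), drivers, rates) == 0.0
        one_row = ann[ann["consequence"] == "stop_gained"].head(1)
        assert driver_substitution_rate(one_row, drivers, rates) == pytest.approx(1e-7)

    def test_empty_driver_set(self):
        ann = enumerate_cds_substitutions(TOY_CDS)
        drivers = DriverConsequenceSet(start_lost=False, stop_lost=False, stop_gained=False)
        assert driver_substitution_rate(ann, drivers, 1e-7) == 0.0

    def test_uniform_rate_counts_stop_gained(self):
        ann = enumerate_cds_substitutions(TOY_CDS)
        drivers = DriverConsequenceSet(start_lost=False, stop_lost=False, stop_gained=True)
        assert driver_substitution_rate(ann, drivers, 1e-7) == pytest.approx(2e-7)

    def test_monotone_in_driver_set(self):
        ann = enumerate_cds_substitutions(TOY_CDS)
        small = DriverConsequenceSet(start_lost=False, stop_lost=False, stop_gained=True)
        big = DriverConsequenceSet(start_lost=True, stop_lost=True, stop_gained=True,
                                   missense=frozenset({(2, "R")}))
        assert driver_substitution_rate(ann, big, 1e-7) >= driver_substitution_rate(ann, small, 1e-7)

    def test_missense_driver_set(self):
        ann = enumerate_cds_substitutions(TOY_CDS)
        # Trp at protein position 2; admit W2R only
        drivers = DriverConsequenceSet(start_lost=False, stop_lost=False, stop_gained=False,
                                       missense=frozenset({(2, "R")}))
        n_w2r = len(ann[(ann["codon_index"] == 1) & (ann["alt_aa"] == "R")])
        assert n_w2r > 0
        assert driver_substitution_rate(ann, drivers, 1e-7) == pytest.approx(n_w2r * 1e-7)


class TestIndelRate:
    def test_exact_slope(self):
        subs = [1000, 2000, 4000]
        indels = [150, 300, 600]
        rate = indel_driver_rate(subs, indels, 87.0, 642, 5.32e9)
        assert rate == pytest.approx(0.15 * 87.0 * 642 / 5.32e9)

    def test_hand_arithmetic(self):
        subs = [1000.0, 2000.0]
        indels = [155.0, 310.0]
        rate = indel_driver_rate(subs, indels, 87.0, 642, 5.32e9)
        assert rate == pytest.approx(87.0 * 0.155 * 642 / 5.32e9, rel=1e-9)
        assert rate == pytest.approx(1.627e-6, rel=1e-3)

    def test_zero_indels(self):
        assert indel_driver_rate([100, 200], [0, 0], 87.0, 642, 5.32e9) == 0.0

    def test_all_zero_substitutions_rejected(self):
        with pytest.raises(ValueError):
            indel_driver_rate([0, 0], [1, 2], 87.0, 642, 5.32e9)


class TestTotal:
    def test_printed_total_at_two_sigfigs(self):
        rates = total_driver_rate(8.5e-7, 1.2e-6)
        assert round_sigfigs(rates.total, 2) == pytest.approx(2.1e-6)

    def test_zero(self):
        assert total_driver_rate(0.0, 0.0).total == 0.0

    def test_commutative(self):
        assert total_driver_rate(1e-7, 3e-7).total == total_driver_rate(3e-7, 1e-7).total

    def test_negative_rejected(self):
        with pytest.raises(ValueError):
            total_driver_rate(-1e-7, 1e-7)


class TestRounding:
    @pytest.mark.parametrize(
        "value,sig,expected",
        [(2.05e-6, 2, 2.1e-6), (0.0, 2, 0.0), (87.4, 2, 87.0), (87.5, 2, 88.0), (0.0345, 2, 0.035)],
    )
    def test_half_away_from_zero(self, value, sig, expected):
        assert round_sigfigs(value, sig) == pytest.approx(expected)


class TestUniformContexts:
    def test_covers_all_contexts(self):
        counts = uniform_context_counts(100.0)
        assert set(counts) == set(all_contexts())
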