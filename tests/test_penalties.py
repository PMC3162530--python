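import pytest

from exonweaver.errors import ConfigurationError
from exonweaver.penalties import PenaltyScheme, intron_penalty, match_penalty


class TestPenaltyScheme:
    def test_canonical_splice_sites_are_free(self, scheme):
        assert scheme.donor("GT") == 0.0
        assert scheme.acceptor("AG") == 0.0

    def test_default_acceptance_is_exactly_gtag_and_gcag(self, scheme):
        donors = ["GT", "GC", "AT", "CA", "TT", "GA"]
        acceptors = ["AG", "AC", "TG", "CC"]
        accepted = {
            (d, a) for d in donors for a in acceptors if scheme.is_accepted(d, a)
        }
        assert accepted == {("GT", "AG"), ("GC", "AG")}

    def test_raising_threshold_admits_atac(self, scheme):
        assert not scheme.is_accepted("AT", "AC")
        relaxed = scheme.with_updates(accepted_intron_penalty=1.5)
        assert relaxed.is_accepted("AT", "AC")

    @pytest.mark.parametrize(
        "kwargs",
        [
            {"mismatch_penalty": -0.1},
            {"min_intron_len": 1},
            {"donor_penalty": {"GT": 0.5}},
            {"acceptor_penalty": {"AG": 0.2}},
        ],
    )
    def test_invalid_configurations_rejected(self, kwargs):
        with pytest.raises(ConfigurationError):
            PenaltyScheme(**kwargs)


class TestIntronPenalty:
    def test_canonical_intron_costs_base_penalty(self, scheme):
        seq = "GT" + "C" * 18 + "AG"
        assert intron_penalty(seq, scheme) == 2.0

    def test_gc_donor_adds_its_penalty(self, scheme):
        seq = "GC" + "C" * 18 + "AG"
        assert intron_penalty(seq, scheme) == 2.0 + scheme.donor("GC")

    def test_below_minimum_length_is_invalid(self, scheme):
        seq = "GT" + "C" * 17 + "AG"  # 21 nt at the default minimum of 22
        assert intron_penalty(seq, scheme) is None


class TestMatchPenalty:
    def test_identity_is_free(self, scheme):
        assert match_penalty("M", "ATG", scheme) == 0.0

    def test_mismatch_costs_one(self, scheme):
        assert match_penalty("K", "ATG", scheme) == 1.0

    def test_stop_codon_scores_as_mismatch(self, scheme):
        assert match_penalty("M", "TAA", scheme) == 1.0

    def test_ambiguous_codon_scores_as_mismatch(self, scheme):
        assert match_penalty("M", "ANG", scheme) == 1.0
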