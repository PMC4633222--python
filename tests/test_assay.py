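"""In-silico digestion, probe derivation and the assay signal model."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from methylarray.assay import (
    ACII,
    HINP1I,
    HPAII,
    METHYL_SENSITIVE_ENZYMES,
    MSEI,
    AssayConfig,
    Fragment,
    SpikeInControl,
    count_sensitive_sites,
    derive_probes,
    digest,
    simulate_assay,
    simulate_methylomes,
    spikein_qc,
)
from methylarray.design import build_design
from methylarray.genome import GenomicInterval, SequenceRecord


def naive_digest_oracle(s: str) -> list[str]:
    """Quadratic position-by-position scan, independent of the find() path."""
    cuts = [i + 1 for i in range(len(s) - 3) if s[i : i + 4] == "TTAA"
            if 0 < i + 1 < len(s)]
    bounds = [0] + cuts + [len(s)]
    return [s[a:b] for a, b in zip(bounds, bounds[1:])]


class TestDigestion:
    @pytest.mark.parametrize(
        "seq,expected",
        [
            ("GGTTAACC", ["GGT", "TAACC"]),
            ("AAAA", ["AAAA"]),
            ("TTAATTAA", ["T", "TAAT", "TAA"]),
            ("TTAA", ["T", "TAA"]),
            ("GGTTANTTAAC", ["GGTTANT", "TAAC"]),  # N never matches
        ],
    )
    def test_known_digestions(self, seq, expected):
        frags = digest(SequenceRecord("x", seq))
        assert [f.residues for f in frags] == expected

    def test_empty_sequence_is_an_error(self):
        with pytest.raises(ValueError):
            SequenceRecord("x", "")

    def test_fragments_tile_the_input_and_record_coordinates(self, rng):
        bases = "".join(rng.choice(list("ACGT"), size=5000))
        frags = digest(SequenceRecord("c", bases))
        assert "".join(f.residues for f in frags) == bases
        pos = 0
        for f in frags:
            assert (f.interval.start, f.interval.end) == (pos, pos + len(f))
            pos += len(f)

    @given(st.text(alphabet="ACGTN", min_size=1, max_size=300))
    @settings(max_examples=200, deadline=None)
    def test_digestion_matches_naive_oracle(self, seq):
        frags = [f.residues for f in digest(SequenceRecord("x", seq))]
        assert frags == naive_digest_oracle(seq)
        assert "".join(frags) == seq


class TestSiteCounting:
    @pytest.mark.parametrize(
        "seq,enzyme,expected",
        [
            ("AACCGGTT", HPAII, 1),
            ("GCGG", ACII, 1),  # reverse complement of CCGC
            ("CCGC", ACII, 1),
            ("AAAATTTT", HPAII, 0),
            ("AAAATTTT", HINP1I, 0),
            ("AAAATTTT", ACII, 0),
            ("GCGCGC", HINP1I, 2),  # overlapping occurrences both count
        ],
    )
    def test_counts(self, seq, enzyme, expected):
        assert count_sensitive_sites(seq, (enzyme,))[enzyme.name] == expected

    def test_empty_fragment_counts_zero(self):
        counts = count_sensitive_sites("A", METHYL_SENSITIVE_ENZYMES)
        assert all(v == 0 for v in counts.values())


class TestProbeDerivation:
    def _frag(self, seq, start=0):
        return Fragment("c", GenomicInterval("c", start, start + len(seq)), seq)

    def test_fragment_without_sites_excluded(self):
        cfg = AssayConfig(amplifiable_range=(2, 100))
        probes = derive_probes([self._frag("ATATATAT")], config=cfg)
        assert probes == []

    def test_length_filter(self):
        cfg = AssayConfig(amplifiable_range=(50, 100))
        too_long = self._frag("CCGG" + "A" * 200)
        assert derive_probes([too_long], config=cfg) == []

    def test_site_counts_recorded(self):
        seq = "CCGG" + "T" * 100 + "CCGG" + "T" * 100 + "GCGG" + "T" * 90
        cfg = AssayConfig(amplifiable_range=(50, 1500))
        (probe,) = derive_probes([self._frag(seq)], config=cfg)
        assert probe.site_count_map() == {"HpaII": 2, "HinP1I": 0, "AciI": 1}

    def test_probe_ids_deterministic(self, toy_probes):
        assert len(set(p.probe_id for p in toy_probes)) == len(toy_probes)


class TestMethylomeSimulation:
    def test_fraction_zero_gives_all_null(self, toy_probes):
        cfg = AssayConfig(seed=3, dmr_fraction=0.0)
        truth = simulate_methylomes(toy_probes, cfg)
        assert (truth.dmr_flags == "null").all().all()

    def test_same_seed_reproduces_truth(self, toy_probes):
        cfg = AssayConfig(seed=5, dmr_fraction=0.1)
        t1 = simulate_methylomes(toy_probes, cfg)
        t2 = simulate_methylomes(toy_probes, cfg)
        pd.testing.assert_frame_equal(t1.dmr_flags, t2.dmr_flags)
        pd.testing.assert_frame_equal(t1.effects, t2.effects)

    def test_planted_count_within_binomial_bounds(self, toy_probes, rng):
        from scipy import stats as st

        cfg = AssayConfig(seed=9, groups=("T",), dmr_fraction=0.05)
        truth = simulate_methylomes(toy_probes, cfg, rng)
        n = len(toy_probes)
        planted = int((truth.dmr_flags["T"] != "null").sum())
        lo, hi = st.binom.interval(0.99, n, 0.05)
        assert lo <= planted <= hi

    def test_null_probes_identical_across_groups(self, toy_probes):
        cfg = AssayConfig(seed=5, dmr_fraction=0.1)
        truth = simulate_methylomes(toy_probes, cfg)
        for pid in truth.probe_ids[:50]:
            if (truth.dmr_flags.loc[pid] == "null").all():
                probs = truth.site_probs[pid]
                for g in cfg.groups:
                    assert np.array_equal(probs[g], probs[cfg.reference])


class TestSignalModel:
    def _noise_free(self, toy_probes, dmr_fraction):
        cfg = AssayConfig(seed=2, groups=("T",), replicates=2, noise_sd=0.0,
                          dye_bias=0.0, dmr_fraction=dmr_fraction)
        truth = simulate_methylomes(toy_probes, cfg)
        design = build_design(cfg.groups, cfg.replicates, cfg.reference)
        intensities, _ = simulate_assay(toy_probes, truth, cfg, design)
        return cfg, truth, design, intensities

    def test_noise_free_log_ratios_equal_planted_effects(self, toy_probes):
        cfg, truth, design, intens = self._noise_free(toy_probes, 0.2)
        real = intens[~intens["is_negative_control"]]
        for _, arr in design.iterrows():
            sub = real[real["array_id"] == arr["array_id"]].set_index("probe_id")
            t, r = ("channel1", "channel2") if arr["dye_swapped"] else ("channel2", "channel1")
            m = np.log2(sub[t] / sub[r])
            expected = truth.effects["T"].reindex(m.index)
            assert np.abs(m - expected).max() < 1e-9

    def test_null_probes_have_zero_ratio_without_noise(self, toy_probes):
        cfg, truth, design, intens = self._noise_free(toy_probes, 0.0)
        real = intens[~intens["is_negative_control"]]
        sub = real[real["array_id"] == design["array_id"].iloc[0]]
        assert np.allclose(np.log2(sub["channel2"] / sub["channel1"]), 0.0)

    def test_same_seed_bitwise_identical_intensities(self, toy_probes):
        cfg = AssayConfig(seed=4, groups=("T",), replicates=2)
        design = build_design(cfg.groups, cfg.replicates, cfg.reference)
        runs = []
        for _ in range(2):
            truth = simulate_methylomes(toy_probes, cfg)
            intens, _ = simulate_assay(toy_probes, truth, cfg, design)
            runs.append(intens)
        pd.testing.assert_frame_equal(runs[0], runs[1])

    def test_treatment_signal_monotone_in_site_methylation(self, toy_probes):
        cfg = AssayConfig(seed=2, groups=("T",), replicates=1, noise_sd=0.0,
                          dye_bias=0.0)
        truth = simulate_methylomes(toy_probes, cfg)
        pid = truth.probe_ids[0]
        base = truth.site_probs[pid]["T"]
        lowered = base.copy()
        lowered[0] *= 0.5
        assert np.prod(lowered) <= np.prod(base)


class TestSpikeInQC:
    @pytest.mark.parametrize(
        "digested,undigested,expected",
        [(30.0, 24.0, "pass"), (29.0, 24.0, "pass"), (28.9, 24.0, "fail")],
    )
    def test_delta_ct_rule(self, digested, undigested, expected):
        ctl = SpikeInControl("c", False, digested, undigested)
        assert spikein_qc(ctl) == expected

    def test_nonpositive_ct_rejected(self):
        with pytest.raises(ValueError):
            SpikeInControl("c", False, -1.0, 24.0)

    def test_simulated_unprotected_controls_pass(self, small_experiment):
        *_, spikeins = small_experiment
        unprotected = [s for s in spikeins if not s.protected]
        assert unprotected and all(spikein_qc(s) == "pass" for s in unprotected)
        protected = [s for s in spikeins if s.protected]
        assert all(spikein_qc(s) == "fail" for s in protected)
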