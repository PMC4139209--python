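"""Seed extraction, site scanning vs a brute-force oracle, ddG scoring."""

import numpy as np
import pytest

from atromir.synthetic_data import (DEFAULT_MATURE_SEQS, SimulationConfig,
                                    simulate_expression, simulate_utrs)
from atromir.target_prediction import (MatureMiRNA, TargetSite, aggregate_score,
                                       duplex_energy, extract_seed,
                                       predict_targets, scan_sites, score_site)

MIR206 = MatureMiRNA("miR-206", "UGGAAUGUAAGGAAGUGUGUGG")
MIR21 = MatureMiRNA("miR-21", "UAGCUUAUCAGACUGAUGUUGA")

_RC = str.maketrans("ACGU", "UGCA")


def revcomp(s: str) -> str:
    return s.translate(_RC)[::-1]


def brute_force_scan(utr: str, seed: str) -> list[int]:
    """Independent oracle: all start positions of the seed's reverse
    complement on the UTR, found by direct string comparison."""
    motif = revcomp(seed)
    return [i for i in range(len(utr) - len(motif) + 1)
            if utr[i:i + len(motif)] == motif]


class TestExtractSeed:
    def test_known_seeds(self):
        assert extract_seed(MIR206) == "GGAAUGU"
        assert extract_seed(MIR21) == "AGCUUAU"

    def test_too_short_sequence_rejected(self):
        with pytest.raises(ValueError):
            extract_seed(MatureMiRNA("x", "ACGUACG"))


class TestScanSites:
    def test_worked_example_site_coordinates(self):
        sites = scan_sites("AAAACAUUCCAAA", MIR206)
        assert [(s.start, s.end) for s in sites] == [(3, 10)]
        assert sites[0].match_type == "7mer-exact"

    def test_empty_utr(self):
        assert scan_sites("", MIR21) == []

    def test_two_abutting_sites(self):
        motif = revcomp(extract_seed(MIR21))
        sites = scan_sites(motif * 2, MIR21)
        assert [(s.start, s.end) for s in sites] == [(0, 7), (7, 14)]

    def test_matches_brute_force_oracle_on_random_sequences(self, rng):
        bases = np.array(list("ACGU"))
        for _ in range(300):
            utr = "".join(bases[rng.integers(0, 4, size=40)])
            mir = MatureMiRNA("m", "".join(bases[rng.integers(0, 4, size=21)]))
            got = [s.start for s in scan_sites(utr, mir)]
            assert got == brute_force_scan(utr, extract_seed(mir))

    def test_gu_policy_superset_of_exact(self, rng):
        bases = np.array(list("ACGU"))
        for _ in range(50):
            utr = "".join(bases[rng.integers(0, 4, size=60)])
            exact = {s.start for s in scan_sites(utr, MIR206)}
            gu = {s.start for s in scan_sites(utr, MIR206, policy="7mer-1GU")}
            assert exact <= gu

    def test_strand_convention_symmetry(self, rng):
        # occurrences of the seed's RC in the UTR equal occurrences of the
        # seed itself in the reverse-complemented UTR
        bases = np.array(list("ACGU"))
        for _ in range(50):
            utr = "".join(bases[rng.integers(0, 4, size=50)])
            seed = extract_seed(MIR21)
            n_fwd = len(brute_force_scan(utr, seed))
            n_rev = len(brute_force_scan(revcomp(utr), revcomp(revcomp(seed))))
            assert n_fwd == n_rev


class TestScoring:
    def test_all_gc_seed_duplex_energy(self):
        # 7 GC pairs at -3.0 plus 6 adjacent stacks at -2.0
        seed = "GGCCGGC"
        window = revcomp(seed)
        assert duplex_energy(window, seed) == pytest.approx(-33.0)

    def test_null_open_model_gives_ddg_equal_duplex(self):
        utr = "AAAACAUUCCAAA"
        (site,) = scan_sites(utr, MIR206)
        score_site(site, utr, MIR206)
        assert site.dG_open == 0.0
        assert site.ddG == site.dG_duplex

    def test_ddg_arithmetic(self):
        # an opening cost of 4 enters as dG_open = -4 and weakens the site
        s = TargetSite("g", "m", 0, 7, dG_duplex=-10.0, dG_open=-4.0)
        assert s.opening_cost == pytest.approx(4.0)
        assert s.ddG == pytest.approx(-6.0)

    def test_invalid_interval_rejected(self):
        s = TargetSite("g", "m", 5, 12)
        with pytest.raises(ValueError):
            score_site(s, "ACGU", MIR206)


class TestAggregateScore:
    def test_single_site_reduces_to_its_score(self):
        assert aggregate_score([-5.33]) == pytest.approx(-5.33)

    def test_two_equal_sites_closed_form(self):
        assert aggregate_score([-1.0, -1.0]) == pytest.approx(-1.0 - np.log(2))

    def test_numerically_stable_for_dominant_site(self):
        assert aggregate_score([-1.0, -100.0]) == pytest.approx(-100.0, abs=1e-10)

    def test_permutation_invariant_and_strengthening(self, rng):
        for _ in range(20):
            ddgs = list(rng.normal(-3, 2, size=rng.integers(1, 6)))
            shuffled = list(rng.permutation(ddgs))
            assert aggregate_score(ddgs) == pytest.approx(aggregate_score(shuffled))
            assert aggregate_score(ddgs + [-1.0]) < aggregate_score(ddgs)
            assert aggregate_score(ddgs) <= min(ddgs) + 1e-12

    def test_empty_rejected(self):
        with pytest.raises(ValueError):
            aggregate_score([])


@pytest.fixture(scope="module")
def planted():
    cfg = SimulationConfig(n_mirna=20, n_mrna=80, replicates=2,
                           targets_per_mirna=5, shared_targets=2,
                           n_program_mrna=5, signature_mirnas_per_block=2,
                           rng_seed=9)
    _, _, truth = simulate_expression(cfg)
    utrs = simulate_utrs(truth, utr_length=150, rng_seed=9)
    return truth, utrs


class TestPredictTargets:

    def test_recovers_exactly_the_planted_targets(self, planted):
        truth, utrs = planted
        mirnas = [MatureMiRNA(m, DEFAULT_MATURE_SEQS[m]) for m in truth.targets]
        preds, unevaluated = predict_targets(utrs, mirnas)
        assert unevaluated == []
        got = {m: {p.gene_id for p in preds if p.mirna == m}
               for m in truth.targets}
        assert got == {m: set(g) for m, g in truth.targets.items()}
        by_pair = {(p.gene_id, p.mirna): p for p in preds}
        for m, genes in truth.targets.items():
            for g in genes:
                assert by_pair[(g, m)].n_sites == truth.n_sites(g, m)

    def test_minus_infinity_cutoff_empties_predictions(self, planted):
        _, utrs = planted
        preds, _ = predict_targets(utrs, [MIR206], cutoff=-np.inf)
        assert preds == []

    def test_shared_seed_mirnas_get_identical_site_lists(self, planted):
        _, utrs = planted
        twin = MatureMiRNA("miR-1", "UGGAAUGUAAAGAAGUAUGUAU")  # same 2-8 seed
        assert extract_seed(twin) == extract_seed(MIR206)
        p1, _ = predict_targets(utrs, [MIR206])
        p2, _ = predict_targets(utrs, [twin])
        assert [(p.gene_id, p.n_sites) for p in p1] == \
               [(p.gene_id, p.n_sites) for p in p2]

    def test_missing_utr_recorded_not_skipped(self):
        preds, unevaluated = predict_targets({"g1": ""}, [MIR206])
        assert preds == [] and unevaluated == ["g1"]


class TestOpenEnergyBackends:
    def test_au_proxy_monotone_in_gc_content(self):
        from atromir.target_prediction import au_content_open_energy
        site = "ACAUUCC"
        low = au_content_open_energy("AAAA" + site + "AAAA", 4, 11)
        high = au_content_open_energy("GGGG" + site + "GGGG", 4, 11)
        assert 0 <= low < high

    def test_vienna_backend_charges_structured_sites_more(self):
        pytest.importorskip("RNA")
        from atromir.target_prediction import vienna_open_energy
        site = "ACAUUCC"
        # a site locked in a hairpin stem (paired to its own reverse
        # complement) costs more to open than one in an unstructured context
        stem = site + "GAAA" + revcomp(site)
        open_ctx = "AUAUAUAUAU" + site + "AUAUAUAUAU"
        c_open = vienna_open_energy(open_ctx, 10, 17)
        c_stem = vienna_open_energy(stem, 0, 7)
        assert c_open >= 0.0
        assert c_stem > c_open
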