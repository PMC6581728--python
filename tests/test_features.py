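import math

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from splicevol.features import (
    EffectSizeInput,
    build_ss_model,
    effect_size,
    find_branch_site,
    find_tract,
    hexamer_enrichment,
    junction_distances,
    scan_candidate_ss,
)
from splicevol.pipeline import feature_matrix

# ---------------------------------------------------------------------------
# independent oracles


def brute_force_tract(window, kind):
    """Enumerate every substring; same rule text, independent code path."""
    alphabet = {"polypyrimidine": "CT", "UA": "AT"}[kind]
    n = len(window)
    best = None  # (length, end, start)
    for s in range(n):
        for e in range(s + 5, n + 1):
            sub = window[s:e]
            comp = sum(sub.count(c) for c in alphabet) / len(sub)
            if comp <= 0.85:
                continue
            if kind == "polypyrimidine" and (e - 1) < n - 10:
                continue
            key = (len(sub), e)
            if best is None or key > (best[0], best[1]):
                best = (len(sub), e, s)
    return None if best is None else (best[2], best[1])


def brute_force_branch(intron):
    window = intron[:-2][-100:]
    pats = {"NNYTRAY", "NNCTYAC", "NNRTAAC", "NNCTAAA"}
    iupac = {"N": "ACGT", "Y": "CT", "R": "AG", "A": "A", "C": "C", "T": "T", "G": "G"}
    hits = []
    for p in range(len(window) - 6):
        h = window[p : p + 7]
        if any(c not in "ACGT" for c in h):
            continue
        for pat in pats:
            if all(b in iupac[q] for b, q in zip(h, pat)):
                mm = sum(x != y for x, y in zip(h, "TACTAAC"))
                hits.append((p, mm))
                break
    if not hits:
        return None
    last = max(hits)
    best = min(mm for _, mm in hits)
    if last[1] != best:
        return None
    return last


# ---------------------------------------------------------------------------


class TestFindTract:
    def test_pure_pyrimidine_tail(self):
        window = "A" * 41 + "TTTTCTTTT"
        hit = find_tract(window, "polypyrimidine")
        assert hit is not None
        assert hit.length >= 9 and hit.composition > 0.85
        assert hit.end == len(window)

    def test_run_of_four_rejected(self):
        window = "GAGAGGAGAGGAGAGGAGAGGAGAGGAGAGGAGAGGAGAGGAGATTTTG"
        assert find_tract(window, "polypyrimidine") is None

    def test_tract_too_far_from_end_rejected_for_ppt(self):
        window = "G" * 25 + "TTTTTTTT" + "G" * 17  # ends 17 nt before window end
        assert find_tract(window, "polypyrimidine") is None
        # the UA rule has no end-position requirement, so the T-run qualifies
        ua = find_tract(window, "UA")
        assert ua is not None and ua.start == 25

    def test_ua_exempt_from_end_rule(self):
        window = "G" * 25 + "ATATATAT" + "G" * 17
        hit = find_tract(window, "UA")
        assert hit is not None and hit.start == 25

    def test_oracle_equivalence_random_windows(self):
        rng = np.random.default_rng(0)
        for _ in range(1000):
            window = "".join(rng.choice(list("ACGT"), size=50))
            for kind in ("polypyrimidine", "UA"):
                hit = find_tract(window, kind)
                oracle = brute_force_tract(window, kind)
                if oracle is None:
                    assert hit is None
                else:
                    assert hit is not None
                    assert (hit.start, hit.end) == oracle

    @given(st.text(alphabet="ACGT", min_size=5, max_size=60))
    @settings(max_examples=200, deadline=None)
    def test_oracle_equivalence_property(self, window):
        for kind in ("polypyrimidine", "UA"):
            hit = find_tract(window, kind)
            oracle = brute_force_tract(window, kind)
            got = None if hit is None else (hit.start, hit.end)
            assert got == oracle


class TestFindBranchSite:
    def test_perfect_consensus(self):
        intron = "G" * 60 + "TACTAAC" + "G" * 28 + "CCAG"
        hit = find_branch_site(intron)
        assert hit is not None
        assert hit.heptamer == "TACTAAC" and hit.mismatches == 0

    def test_downstream_worse_hit_discards_intron(self):
        # upstream perfect consensus, downstream degenerate 3-mismatch hit
        intron = "G" * 40 + "TACTAAC" + "G" * 20 + "CCCTCAC" + "G" * 20 + "AG"
        assert find_branch_site(intron) is None

    def test_no_heptamer(self):
        assert find_branch_site("G" * 80 + "AG") is None

    def test_oracle_equivalence_random_introns(self):
        rng = np.random.default_rng(1)
        for _ in range(1000):
            intron = "".join(rng.choice(list("ACGT"), size=int(rng.integers(50, 160))))
            hit = find_branch_site(intron)
            oracle = brute_force_branch(intron)
            if oracle is None:
                assert hit is None
            else:
                assert hit is not None
                assert (hit.position, hit.mismatches) == oracle


class TestEffectSize:
    def test_hand_computed(self):
        val = effect_size(EffectSizeInput(20, 100, 10, 100))
        assert val == pytest.approx(math.log2(2.25), abs=1e-9)
        assert val == pytest.approx(1.1699, abs=1e-4)

    def test_equal_frequencies_zero(self):
        assert effect_size(EffectSizeInput(7, 50, 7, 50)) == 0.0

    def test_zero_cell_pseudocount_finite(self):
        val = effect_size(EffectSizeInput(0, 100, 10, 100))
        assert math.isfinite(val) and val < 0

    def test_antisymmetry(self):
        a = effect_size(EffectSizeInput(20, 100, 5, 80))
        b = effect_size(EffectSizeInput(5, 80, 20, 100))
        assert a == pytest.approx(-b)

    @given(
        st.integers(0, 50),
        st.integers(1, 50),
        st.integers(0, 50),
        st.integers(1, 50),
    )
    @settings(max_examples=200, deadline=None)
    def test_identity_and_antisymmetry_property(self, k1, extra1, k2, extra2):
        n1, n2 = k1 + extra1, k2 + extra2
        assert effect_size(EffectSizeInput(k1, n1, k1, n1)) == 0.0
        fwd = effect_size(EffectSizeInput(k1, n1, k2, n2))
        rev = effect_size(EffectSizeInput(k2, n2, k1, n1))
        assert fwd == pytest.approx(-rev, abs=1e-12)

    def test_invalid_counts(self):
        with pytest.raises(ValueError):
            EffectSizeInput(5, 3, 1, 10)


class TestSpliceSiteModel:
    def test_point_mass_on_identical_positives(self):
        model = build_ss_model(["ACGTAGTACGTA"] * 100, ["ACGTAGTACGTA"] * 100)
        for i, base in enumerate("ACGTAGTACGTA"):
            col = model.pwm[i]
            assert col["ACGT".index(base)] > 0.9
        assert np.allclose(model.pwm.sum(axis=1), 1.0)

    def test_background_equals_positives_scores_near_zero(self):
        rng = np.random.default_rng(2)
        seqs = ["".join(rng.choice(list("ACGT"), size=12)) for _ in range(400)]
        model = build_ss_model(seqs, seqs)
        scores = [model.score(s) for s in seqs[:100]]
        assert abs(float(np.mean(scores))) < 0.5

    def test_authentic_dinucleotide_columns_dominate(self, cohort_basic):
        # count frequencies on true donor sites from the synthetic genome
        from splicevol.features import FeatureContext, default_ss_models
        from splicevol.pipeline import species_junctions

        c = cohort_basic
        ctx = FeatureContext(genome=c.genomes["sp0"], gene_models=c.gene_models["sp0"])
        js = species_junctions(c, "sp0")
        models = default_ss_models(js, ctx)
        five = models["5prime"].pwm
        assert five[5, 2] > 0.9 and five[6, 3] > 0.9  # G, T
        three = models["3prime"].pwm
        assert three[5, 0] > 0.9 and three[6, 2] > 0.9  # A, G

    def test_scan_requires_anchor(self):
        model = build_ss_model(["AAAAAGTAAAAA"] * 50, ["CCCCCCCCCCCC"] * 50)
        assert scan_candidate_ss("ACACACACACACACAC", model) == []

    def test_scan_infinite_threshold_empty(self):
        model = build_ss_model(["AAAAAGTAAAAA"] * 50, ["CCCCCCCCCCCC"] * 50)
        seq = "AAAAAGTAAAAAAAAAAGTAAAAA"
        assert scan_candidate_ss(seq, model, threshold=math.inf) == []

    def test_training_consensus_retained(self):
        model = build_ss_model(["AACCAGTTTGGA"] * 60, ["CAGTCAGTCAGT"] * 60)
        hits = scan_candidate_ss("AACCAGTTTGGA", model)
        assert len(hits) == 1 and hits[0].match_score > 2

    def test_window_length_validation(self):
        with pytest.raises(ValueError):
            build_ss_model(["ACGT"], ["ACGTACGTACGT"])


class TestJunctionDistances:
    def test_internal_gt_frame_preserving(self):
        intron = "GT" + "A" * 10 + "GT" + "A" * 50 + "AG"  # GT at distance 12
        d = junction_distances(intron, "5prime")
        assert d.inter_distance == 12 and not d.inter_frameshift

    def test_internal_ag_frameshifting(self):
        intron = "GT" + "C" * 55 + "AG" + "CCCCC" + "AG"  # AG ending 7 nt early
        d = junction_distances(intron, "3prime")
        assert d.inter_distance == 7 and d.inter_frameshift

    def test_absent_state(self):
        intron = "GT" + "A" * 40 + "AG"
        d = junction_distances(intron, "5prime")
        assert d.inter_distance is None and not d.inter_present
        assert d.alt_ss_distance is None and not d.alt_ss_present

    def test_junction_size(self):
        intron = "GT" + "A" * 40 + "AG"
        assert junction_distances(intron, "5prime").junction_size == len(intron)

    def test_candidate_distances_used(self):
        intron = "GT" + "A" * 40 + "AG"
        d = junction_distances(intron, "5prime", candidate_distances=[9, 21])
        assert d.alt_ss_distance == 9 and not d.alt_ss_frameshift
        d2 = junction_distances(intron, "5prime", candidate_distances=[10])
        assert d2.alt_ss_distance == 10 and d2.alt_ss_frameshift


class TestHexamerEnrichment:
    def _windows(self, rng, n, planted=None, p=0.0):
        out = []
        for _ in range(n):
            w = "".join(rng.choice(list("ACGT"), size=50))
            if planted and rng.random() < p:
                pos = int(rng.integers(0, 44))
                w = w[:pos] + planted + w[pos + 6 :]
            out.append(w)
        return out

    def test_planted_motif_enriched(self):
        rng = np.random.default_rng(3)
        pos = self._windows(rng, 200, planted="TTAGCA", p=0.8)
        bg = self._windows(rng, 400, planted="TTAGCA", p=0.05)
        table = hexamer_enrichment(pos, bg, seed=0)
        row = table[table["motif"] == "TTAGCA"].iloc[0]
        assert row["direction"] == "enhancer"
        assert row["p_adjusted"] < 0.01

    def test_null_no_motif_passes(self):
        rng = np.random.default_rng(4)
        win = self._windows(rng, 300)
        table = hexamer_enrichment(win, win, seed=0)
        assert not table["significant"].any()

    def test_background_subsampled_to_max(self):
        rng = np.random.default_rng(5)
        pos = self._windows(rng, 20)
        bg = self._windows(rng, 150)
        table = hexamer_enrichment(pos, bg, max_background=100, seed=0)
        assert int(table["n_background"].max()) <= 100
        # totals are consistent with exactly 100 background windows used
        present_everywhere = table[table["n_positive"] == 20]
        assert (present_everywhere["n_background"] <= 100).all()


class TestFeatureMatrix:
    def test_low_support_excluded(self, cohort_signal):
        m = feature_matrix(cohort_signal, "sp0", "AltA")
        assert (m["mean_reads"] >= 5).all()

    def test_labels_and_columns(self, cohort_signal):
        m = feature_matrix(cohort_signal, "sp0", "AltA")
        assert set(m["label"]) == {"alternative", "constitutive"}
        assert "inter_ag_distance" in m.columns and "junction_size" in m.columns

    def test_planted_distance_separates_labels(self, cohort_signal):
        m = feature_matrix(cohort_signal, "sp0", "AltA")
        alt = m[m["label"] == "alternative"]["inter_ag_distance"].mean()
        con = m[m["label"] == "constitutive"]["inter_ag_distance"].mean()
        assert alt < con

    def test_monotone_as_frequency_across_distance_bins(self, cohort_signal):
        """AS frequency decreases with alternative-SS distance (planted)."""
        c = cohort_signal
        jt = c.junction_truth
        jt = jt[jt["as_type"].isin(["AltA", "none"])]
        bins = [5, 15, 25, 37]
        freqs = []
        for lo, hi in zip(bins[:-1], bins[1:]):
            grp = jt[(jt["d_planted"] > lo) & (jt["d_planted"] <= hi)]
            freqs.append(grp["has_as"].mean())
        assert all(a >= b for a, b in zip(freqs[:-1], freqs[1:]))
        assert freqs[0] > freqs[-1]

    def test_multi_type_junction_excluded(self, cohort_basic):
        m = feature_matrix(cohort_basic, "sp0", "AltA")
        # no junction with an event of another type may appear
        truth = cohort_basic.truth
        other = truth[(truth["species"] == "sp0") & (truth["as_type"] != "AltA")]
        other_ids = {
            f"{r.chrom}:{r.authentic_start}-{r.authentic_end}:{r.strand}"
            for r in other.itertuples()
        }
        assert not (set(m["junction_id"]) & other_ids)
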