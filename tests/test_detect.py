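"""The compositional detector: ORF calling, window features, classifier,
region assembly, boundary refinement, and verification."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from lysoscape import (
    GenomeRecord,
    OrfFeature,
    SyntheticSpec,
    assemble_regions,
    call_orfs,
    compute_skews,
    generate_cohort,
    kmer_phage_score,
    refine_boundaries,
    train_classifier,
    verify_region,
    window_metrics,
)
from lysoscape.detect import (
    FEATURE_COLUMNS,
    ProphageRegion,
    detect,
    label_orfs_by_truth,
    orf_feature_table,
)
from lysoscape.report import regions_to_frame


# ---------------------------------------------------------------------------
# ORF calling

def _brute_force_orfs(seq, min_len):
    """Six-frame oracle: maximal ATG->stop ORFs by direct enumeration."""
    comp = str.maketrans("ACGT", "TGCA")
    stops = {"TAA", "TAG", "TGA"}
    found = set()
    for strand, s in ((1, seq), (-1, seq.translate(comp)[::-1])):
        n = len(s)
        for frame in range(3):
            codons = [s[i : i + 3] for i in range(frame, n - 2, 3)]
            prev_stop = -1
            for ci, codon in enumerate(codons):
                if codon in stops:
                    for q in range(prev_stop + 1, ci):
                        if codons[q] == "ATG":
                            a = frame + q * 3
                            b = frame + ci * 3 + 3
                            if b - a >= min_len:
                                if strand == 1:
                                    found.add((a, b, 1))
                                else:
                                    found.add((n - b, n - a, -1))
                            break
                    prev_stop = ci
    return found


class TestCallOrfs:
    def test_single_constructed_orf(self):
        seq = "ATG" + "AAA" * 98 + "TAA"  # 300 bp, one forward ORF
        orfs = call_orfs(seq, min_orf_len=90)
        forward = [o for o in orfs if o.strand == 1]
        assert any((o.start, o.end) == (0, 300) for o in forward)

    def test_all_n_sequence_empty(self):
        assert call_orfs("N" * 600) == []

    @given(st.integers(0, 10_000))
    @settings(max_examples=30)
    def test_matches_bruteforce_six_frame_scan(self, seed):
        rng = np.random.default_rng(seed)
        seq = "".join(rng.choice(list("ACGT"), size=400))
        got = {(o.start, o.end, o.strand) for o in call_orfs(seq, min_orf_len=60)}
        assert got == _brute_force_orfs(seq, 60)

    def test_sorted_by_start(self):
        rng = np.random.default_rng(1)
        seq = "".join(rng.choice(list("ACGT"), size=3000))
        orfs = call_orfs(seq, min_orf_len=60)
        starts = [o.start for o in orfs]
        assert starts == sorted(starts)


# ---------------------------------------------------------------------------
# raw signals

class TestSkews:
    def _one_orf(self, seq):
        return [OrfFeature("c", 0, len(seq), 1)]

    def test_pure_g_span(self):
        devs = compute_skews("GGGG", self._one_orf("GGGG"), (0.0, 0.0))
        assert devs[0][0] == pytest.approx(1.0)

    def test_balanced_gc_span(self):
        devs = compute_skews("GCGC", self._one_orf("GCGC"), (0.0, 0.0))
        assert devs[0][0] == pytest.approx(0.0)

    def test_pure_t_span_with_baseline(self):
        devs = compute_skews("TTTT", self._one_orf("TTTT"), (0.0, 0.2))
        assert devs[0][1] == pytest.approx(-1.2)
        assert devs[0][0] == pytest.approx(0.0)  # no G+C content -> skew 0


class TestKmerScore:
    def test_no_markers_scores_zero(self):
        assert kmer_phage_score("A" * 50, {"G" * 12}) == 0.0

    def test_all_positions_markers(self):
        marker = "A" * 12
        seq = "A" * 30  # every 12-mer window equals the marker
        assert kmer_phage_score(seq, {marker}) == 1.0

    def test_two_marker_positions_of_nine(self):
        # 20-mer: marker at positions 0 and 8 (and nowhere else) -> 2/9
        marker = "AACCGGTTAACC"
        seq = marker + "GGTTAACC"
        seq = seq[:8] + marker  # positions 0..8; re-check by enumeration
        hits = sum(seq[i : i + 12] == marker for i in range(len(seq) - 11))
        assert len(seq) == 20 and hits == 2
        assert kmer_phage_score(seq, {marker}) == pytest.approx(2 / 9)

    def test_short_orf_scores_zero(self):
        assert kmer_phage_score("ACGT", {"A" * 12}) == 0.0


# ---------------------------------------------------------------------------
# window metrics

def _raw_frame(lengths, strands, scores=None):
    n = len(lengths)
    starts = np.cumsum([0] + [l + 50 for l in lengths[:-1]])
    return pd.DataFrame(
        dict(
            contig_id="c",
            start=starts,
            end=starts + np.array(lengths),
            strand=strands,
            length=lengths,
            annotation="",
            kmer_score_raw=scores if scores is not None else np.zeros(n),
            gc_dev_raw=np.zeros(n),
            at_dev_raw=np.zeros(n),
        )
    )


class TestWindowMetrics:
    def test_median_length_window_of_three(self):
        out = window_metrics(_raw_frame([300, 600, 900], [1, 1, 1]), window_size=3)
        assert out.loc[1, "median_orf_len"] == 600

    def test_uniform_strand_run_is_one(self):
        out = window_metrics(_raw_frame([500] * 30, [1] * 30), window_size=30)
        assert out["same_strand_run"].to_numpy() == pytest.approx(np.ones(30))

    def test_alternating_strands_run_fraction(self):
        strands = [1, -1] * 15
        out = window_metrics(_raw_frame([500] * 30, strands), window_size=30)
        # central ORF sees the full 30-ORF window; longest run is 1
        assert out.loc[15, "same_strand_run"] == pytest.approx(1 / 30)

    def test_windows_truncate_at_contig_ends(self):
        out = window_metrics(_raw_frame([500] * 10, [1] * 10), window_size=30)
        assert len(out) == 10
        assert np.isfinite(out[list(FEATURE_COLUMNS)].to_numpy()).all()


# ---------------------------------------------------------------------------
# classifier

class TestClassifier:
    def _separable(self, n=300, seed=0):
        rng = np.random.default_rng(seed)
        half = n // 2
        host = pd.DataFrame(
            {
                "median_orf_len": rng.normal(900, 50, half),
                "same_strand_run": rng.uniform(0.1, 0.3, half),
                "phage_kmer_score": rng.uniform(0, 1e-4, half),
                "gc_skew_dev": rng.normal(0, 0.02, half),
                "at_skew_dev": rng.normal(0, 0.02, half),
            }
        )
        phage = pd.DataFrame(
            {
                "median_orf_len": rng.normal(600, 50, half),
                "same_strand_run": rng.uniform(0.7, 1.0, half),
                "phage_kmer_score": rng.uniform(0.003, 0.008, half),
                "gc_skew_dev": rng.normal(0.25, 0.02, half),
                "at_skew_dev": rng.normal(-0.2, 0.02, half),
            }
        )
        X = pd.concat([host, phage], ignore_index=True)
        y = np.array([0] * half + [1] * half)
        return X, y

    def test_separable_features_high_oob(self):
        X, y = self._separable()
        model = train_classifier(X, y, n_trees=200, seed=0)
        assert model.forest.oob_score_ >= 0.95

    def test_shuffled_labels_near_chance(self):
        X, y = self._separable(n=400, seed=1)
        rng = np.random.default_rng(2)
        model = train_classifier(X, rng.permutation(y), n_trees=200, seed=0)
        assert abs(model.forest.oob_score_ - 0.5) <= 0.1

    def test_deterministic_under_seed(self):
        X, y = self._separable()
        a = train_classifier(X, y, n_trees=100, seed=5).predict_proba(X)
        b = train_classifier(X, y, n_trees=100, seed=5).predict_proba(X)
        np.testing.assert_array_equal(a, b)

    def test_single_class_rejected(self):
        X, y = self._separable()
        with pytest.raises(ValueError, match="both classes"):
            train_classifier(X, np.zeros_like(y), seed=0)

    def test_schema_mismatch_rejected(self):
        X, y = self._separable()
        model = train_classifier(X, y, n_trees=50, seed=0)
        with pytest.raises(ValueError, match="lacks columns"):
            model.predict(X.drop(columns=["at_skew_dev"]))


# ---------------------------------------------------------------------------
# region assembly

def _pred_table(pattern):
    lengths = [600] * len(pattern)
    return _raw_frame(lengths, [1] * len(pattern)), np.array(
        [c == "P" for c in pattern]
    )


class TestAssembleRegions:
    def test_six_consecutive_phage_orfs(self):
        table, pred = _pred_table("PPPPPP")
        regions = assemble_regions(table, pred)
        assert len(regions) == 1
        assert regions[0].n_genes == 6 and regions[0].status == "pending"

    def test_four_orfs_discarded_too_few(self):
        table, pred = _pred_table("PPPP")
        (region,) = assemble_regions(table, pred)
        assert region.status == "discarded" and region.discard_reason == "too_few_genes"

    def test_gap_tolerance_merges_or_splits(self):
        table, pred = _pred_table("PPPHPP")
        (merged,) = assemble_regions(table, pred, gap_tolerance=1)
        assert merged.n_genes == 5 and merged.status == "pending"
        split = assemble_regions(table, pred, gap_tolerance=0)
        assert len(split) == 2
        assert [r.n_genes for r in split] == [3, 2]
        assert all(r.status == "discarded" for r in split)

    def test_span_is_first_to_last_phage_orf(self):
        table, pred = _pred_table("HPPPPPH")
        (region,) = assemble_regions(table, pred)
        assert region.start == table.loc[1, "start"]
        assert region.end == table.loc[5, "end"]


# ---------------------------------------------------------------------------
# boundary refinement

class TestRefineBoundaries:
    def test_planted_att_pair_snaps_exactly(self, unique_dna):
        att = unique_dna[60_000 : 60_012]  # 12 bp, absent from the segments below
        left = unique_dna[0:3000]
        core = unique_dna[10_000:19_000]
        right = unique_dna[25_000:28_000]
        seq = left + att + core + att + right
        true_start, true_end = 3000, 3000 + 12 + 9000 + 12
        region = ProphageRegion("c", true_start + 700, true_end - 900, n_genes=10)
        out = refine_boundaries(region, seq)
        assert (out.start, out.end) == (true_start, true_end)
        assert out.att_repeat == (3000, 3000 + 12 + 9000, 12)

    def test_no_repeat_leaves_region_unchanged(self, unique_dna):
        seq = unique_dna[0:12_000]
        region = ProphageRegion("c", 4000, 8000, n_genes=10)
        out = refine_boundaries(region, seq)
        assert (out.start, out.end) == (4000, 8000) and out.att_repeat is None

    def test_longest_pair_wins_then_displacement(self, unique_dna):
        rep10 = unique_dna[60_000 : 60_010]
        rep14 = unique_dna[62_000 : 62_014]
        left = (
            unique_dna[0:1500] + rep10 + unique_dna[2000:2200] + rep14
            + unique_dna[3000:3176]
        )
        assert len(left) == 1900
        core = unique_dna[10_000:15_000]
        right = rep14 + unique_dna[20_000:20_300] + rep10 + unique_dna[25_000:26_500]
        seq = left + core + right
        region = ProphageRegion("c", 1900, 1900 + 5000, n_genes=10)
        out = refine_boundaries(region, seq)
        assert out.att_repeat is not None
        assert out.att_repeat[2] == 14  # the longer pair is chosen
        assert seq[out.start : out.start + 14] == rep14

    def test_flanks_clipped_at_contig_edges(self, unique_dna):
        seq = unique_dna[0:5000]
        region = ProphageRegion("c", 100, 4900, n_genes=10)
        out = refine_boundaries(region, seq)  # must not raise
        assert out.end <= len(seq)


# ---------------------------------------------------------------------------
# verification

class TestVerifyRegion:
    def _table(self, annotations):
        n = len(annotations)
        t = _raw_frame([600] * n, [1] * n)
        t["annotation"] = annotations
        return t

    def test_one_phage_annotation_keeps_region(self):
        t = self._table(["x"] * 5 + ["phage major capsid protein"])
        region = ProphageRegion("c", 0, 3900, n_genes=6, orf_rows=list(range(6)))
        out = verify_region(region, t, np.zeros(6, dtype=bool))
        assert out.status == "kept" and out.phage_annotated_genes == 1

    def test_no_evidence_discards(self):
        t = self._table(["hypothetical protein"] * 6)
        region = ProphageRegion("c", 0, 3900, n_genes=6, orf_rows=list(range(6)))
        out = verify_region(region, t, np.zeros(6, dtype=bool))
        assert out.status == "discarded" and out.discard_reason == "no_phage_evidence"

    def test_provider_hit_keeps_region_and_fraction(self):
        t = self._table(["x"] * 6)
        region = ProphageRegion(
            "c", int(t.loc[0, "start"]), int(t.loc[5, "end"]), n_genes=6,
            orf_rows=list(range(6)),
        )
        hits = np.array([True, True, True, False, False, False])
        out = verify_region(region, t, hits)
        assert out.status == "kept"
        expected = 1800 / region.length  # 3 x 600 bp of hit ORFs
        assert out.verified_bp_fraction == pytest.approx(expected)

    def test_half_region_hit_fraction(self):
        t = _raw_frame([10_000, 10_000], [1, 1])
        t["annotation"] = ""
        region = ProphageRegion(
            "c", int(t.loc[0, "start"]), int(t.loc[1, "end"]), n_genes=6,
            orf_rows=[0, 1],
        )
        out = verify_region(region, t, np.array([True, False]))
        assert out.verified_bp_fraction == pytest.approx(10_000 / region.length)


# ---------------------------------------------------------------------------
# full pipeline properties

@pytest.fixture(scope="module")
def lysogen(model, run_config, hit_provider, marker_vocab):
    spec = SyntheticSpec(n_genomes=1, seed=404)
    records, _, truth = generate_cohort(spec)
    return records[0], truth, model, run_config, hit_provider, marker_vocab[1]


class TestDetectPipeline:
    def test_recovers_planted_prophages(self, lysogen):
        rec, truth, model, cfg, provider, codes = lysogen
        regions = detect(rec, model, cfg, provider, marker_codes=codes)
        kept = [r for r in regions if r.status == "kept"]
        assert len(kept) == len(truth.regions)
        for r in kept:
            assert r.n_genes >= cfg.number

    def test_kept_regions_disjoint_and_within_contigs(self, lysogen):
        rec, _, model, cfg, provider, codes = lysogen
        regions = sorted(
            (r for r in detect(rec, model, cfg, provider, marker_codes=codes)
             if r.status == "kept"),
            key=lambda r: r.start,
        )
        lens = rec.contig_lengths
        for a, b in zip(regions, regions[1:]):
            assert a.end <= b.start
        for r in regions:
            assert 0 <= r.start < r.end <= lens[r.contig_id]

    def test_invariant_under_contig_reordering(self, lysogen):
        rec, _, model, cfg, provider, codes = lysogen
        # split the genome into two contigs, then present them in both orders
        cid, seq = rec.contigs[0]
        cut = len(seq) // 2
        feats_a = [f for f in rec.cds if f.end <= cut]
        feats_b = [
            OrfFeature("cB", f.start - cut, f.end - cut, f.strand, f.annotation)
            for f in rec.cds
            if f.start >= cut
        ]
        for f in feats_a:
            f = f  # features already on cid; rename below
        contigs = [("cA", seq[:cut]), ("cB", seq[cut:])]
        feats = [
            OrfFeature("cA", f.start, f.end, f.strand, f.annotation) for f in feats_a
        ] + feats_b
        fwd = GenomeRecord("X", contigs, feats)
        rev = GenomeRecord("X", contigs[::-1], feats)
        out1 = regions_to_frame("X", detect(fwd, model, cfg, provider, marker_codes=codes))
        out2 = regions_to_frame("X", detect(rev, model, cfg, provider, marker_codes=codes))
        pd.testing.assert_frame_equal(out1, out2)

    def test_threshold_monotonicity(self, lysogen):
        import dataclasses

        rec, _, model, cfg, provider, codes = lysogen
        kept_bp = []
        for th in (0.3, 0.5, 0.7, 0.9):
            m = dataclasses.replace(model, threshold=th)
            regions = detect(rec, m, cfg, provider, marker_codes=codes)
            kept_bp.append(sum(r.length for r in regions if r.status == "kept"))
        assert all(a >= b for a, b in zip(kept_bp, kept_bp[1:]))

    def test_all_short_contigs_yield_empty(self, model, run_config, hit_provider, marker_vocab):
        rec = GenomeRecord("S", [("c1", "ACGT" * 1000)])  # 4 kbp < min_contig_len
        out = detect(rec, model, run_config, hit_provider, marker_codes=marker_vocab[1])
        assert out == []

    def test_orf_labelling_by_truth_midpoints(self, lysogen):
        rec, truth, model, cfg, provider, codes = lysogen
        table = orf_feature_table(rec, codes)
        labels = label_orfs_by_truth(table, truth.regions)
        assert labels.sum() > 0
        mids = (table["start"] + table["end"]) // 2
        for _, r in truth.regions.iterrows():
            inside = (mids >= r.start) & (mids < r.end)
            assert labels[inside.to_numpy()].all()
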