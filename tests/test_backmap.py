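"""The read-backmapping cleanup: extraction, uniqueness filter, re-typing."""

import numpy as np
import pytest

from trbackmap.align import Aligner, AlignmentRecord
from trbackmap.backmap import (
    REASON_NOT_RETYPED,
    VERDICT_CHANGED,
    VERDICT_ELIMINATED,
    VERDICT_RETAINED,
    extract_snp_supporting_reads,
    probe_backmap,
    retype_after_backmap,
    run_backmap,
    unique_over_snp_filter,
)
from trbackmap.intervals import GenomicInterval
from trbackmap.pileup import GenotypeThresholds, VariantCall
from trbackmap.reference import Block, TransformTable, build_tr_reference
from trbackmap.synth import generate_genome


def _variant(pos, genotype=("A", "C"), zygosity="het", supporting=None, ref_base="A"):
    return VariantCall(
        ref_name="TR", pos=pos, ref_base=ref_base, genotype=genotype,
        zygosity=zygosity, depth=sum(len(v) for v in (supporting or {}).values()),
        supporting_reads=supporting or {},
    )


def _mapped(read_id, pos, seq, mate=1, chrom="chr1", strand="+", n_best=1):
    return AlignmentRecord(
        read_id=read_id, mate=mate, ref_name=chrom, pos=pos, strand=strand,
        mapped=True, seq=seq, n_best_hits=n_best,
    )


class TestExtraction:
    def _records(self, ids):
        recs = []
        for rid in ids:
            recs.append(_mapped(rid, 10, "ACGT" * 10, mate=1))
            recs.append(_mapped(rid, 100, "TTTT" * 10, mate=2, strand="-"))
        return recs

    def test_het_variant_pulls_read_pairs_with_mates(self):
        recs = self._records(["r1", "r2"])
        v = _variant(20, supporting={"A": ["r1"], "C": ["r2"]})
        pairs = extract_snp_supporting_reads(recs, [v])
        assert sorted(p.name for p in pairs) == ["r1", "r2"]
        assert all(p.seq2 is not None for p in pairs)

    def test_read_shared_by_two_variants_emitted_once(self):
        recs = self._records(["r1", "r2", "r3"])
        v1 = _variant(20, supporting={"A": ["r1"], "C": ["r2"]})
        v2 = _variant(30, supporting={"A": ["r1"], "C": ["r3"]})
        pairs = extract_snp_supporting_reads(recs, [v1, v2])
        assert sorted(p.name for p in pairs) == ["r1", "r2", "r3"]

    def test_reference_supporting_reads_also_extracted(self):
        """Re-typing needs the reference reads, not only the alt reads."""
        recs = self._records(["ref_read", "alt_read"])
        v = _variant(20, supporting={"A": ["ref_read"], "C": ["alt_read"]})
        assert {p.name for p in extract_snp_supporting_reads(recs, [v])} == {
            "ref_read", "alt_read",
        }

    def test_hom_variants_skipped_unless_requested(self):
        recs = self._records(["r1"])
        v = _variant(20, genotype=("C", "C"), zygosity="hom", supporting={"C": ["r1"]})
        assert extract_snp_supporting_reads(recs, [v]) == []
        assert len(extract_snp_supporting_reads(recs, [v], include_hom=True)) == 1

    def test_empty_support_warns_and_excludes(self, caplog):
        recs = self._records(["r1"])
        v = _variant(20, supporting={})
        with caplog.at_level("WARNING"):
            assert extract_snp_supporting_reads(recs, [v]) == []
        assert "no supporting reads" in caplog.text

    def test_extracted_set_is_union_of_variant_supports(self):
        recs = self._records(["r1", "r2", "r3", "r4"])
        variants = [
            _variant(20, supporting={"A": ["r1", "r2"], "C": ["r3"]}),
            _variant(40, supporting={"A": ["r2"], "C": ["r4"]}),
        ]
        union = {"r1", "r2", "r3", "r4"}
        assert {p.name for p in extract_snp_supporting_reads(recs, variants)} == union


class TestUniqueOverSnpFilter:
    def test_unique_covering_read_survives(self):
        rec = _mapped("r1", 100, "A" * 50)
        out = unique_over_snp_filter([rec], {0: ("chr1", 120)})
        assert out[0] == [rec]

    def test_multi_hit_read_removed_everywhere(self):
        rec = _mapped("r1", 100, "A" * 50, n_best=2)
        out = unique_over_snp_filter([rec], {0: ("chr1", 120), 1: ("chr1", 130)})
        assert out[0] == [] and out[1] == []

    def test_unique_read_no_longer_covering_site_removed(self):
        # best placement shifted away from the variant site
        rec = _mapped("r1", 500, "A" * 50)
        assert unique_over_snp_filter([rec], {0: ("chr1", 120)})[0] == []

    def test_duplicates_excluded(self):
        rec = _mapped("r1", 100, "A" * 50)
        rec.is_duplicate = True
        assert unique_over_snp_filter([rec], {0: ("chr1", 120)})[0] == []


class TestRetype:
    @pytest.fixture()
    def setup(self):
        genome, _ = generate_genome({"chr1": 1000}, seed=50)
        table = TransformTable(blocks=[Block(0, 400, "chr1", 100)], spacer_len=50)
        return genome, table

    def _support_records(self, genome, gpos, n_ref, n_alt, alt):
        recs = []
        for i in range(n_ref + n_alt):
            start = gpos - 20
            seq = list(genome["chr1"][start : start + 50])
            if i < n_alt:
                seq[20] = alt
            recs.append(
                _mapped(f"s{i}", start, "".join(seq), strand="+" if i % 2 else "-")
            )
        return recs

    def test_all_reads_survive_keeps_genotype(self, setup):
        genome, table = setup
        gpos, tr_pos = 300, 200
        ref = genome["chr1"][gpos]
        alt = "A" if ref != "A" else "C"
        recs = self._support_records(genome, gpos, 6, 6, alt)
        v = _variant(tr_pos, genotype=tuple(sorted((ref, alt))),
                     supporting={ref: [r.read_id for r in recs[6:]],
                                 alt: [r.read_id for r in recs[:6]]},
                     ref_base=ref)
        final, removed, report = retype_after_backmap(
            [v], table, {0: recs}, genome, GenotypeThresholds()
        )
        assert report.outcomes[0].verdict == VERDICT_RETAINED
        assert final[0].pos == gpos and final[0].gt_key() == v.gt_key()

    def test_all_reads_removed_eliminates(self, setup):
        genome, table = setup
        v = _variant(200, supporting={"A": ["x1", "x2"]})
        final, removed, report = retype_after_backmap([v], table, {0: []}, genome)
        assert final == [] and len(removed) == 1
        assert report.outcomes[0].verdict == VERDICT_ELIMINATED

    def test_alt_reads_lost_reverts_to_reference(self, setup):
        """The paralog mechanism: alt reads relocate, site re-types hom-ref."""
        genome, table = setup
        gpos, tr_pos = 300, 200
        ref = genome["chr1"][gpos]
        alt = "A" if ref != "A" else "C"
        recs = self._support_records(genome, gpos, 10, 0, alt)
        v = _variant(tr_pos, genotype=tuple(sorted((ref, alt))),
                     supporting={ref: [r.read_id for r in recs], alt: ["gone1", "gone2"]},
                     ref_base=ref)
        final, removed, report = retype_after_backmap([v], table, {0: recs}, genome)
        assert final == []
        assert report.outcomes[0].verdict == VERDICT_ELIMINATED
        assert "reference" in report.outcomes[0].reason

    def test_hom_variant_passes_through_lifted(self, setup):
        genome, table = setup
        v = _variant(200, genotype=("C", "C"), zygosity="hom", supporting={"C": ["r1"]})
        final, removed, report = retype_after_backmap([v], table, {}, genome)
        assert final[0].pos == 300 and final[0].ref_name == "chr1"
        assert report.outcomes[0].reason == REASON_NOT_RETYPED

    def test_report_partition_invariant(self, setup):
        genome, table = setup
        variants = [
            _variant(100, supporting={"A": ["a"]}),
            _variant(200, genotype=("C", "C"), zygosity="hom", supporting={"C": ["b"]}),
            _variant(250, supporting={}),
        ]
        _, _, report = retype_after_backmap(variants, table, {0: []}, genome)
        total = sum(report.count(v) for v in (VERDICT_RETAINED, VERDICT_ELIMINATED, VERDICT_CHANGED))
        assert total == report.n_initial == 3
        assert 0.0 <= report.elimination_fraction <= 1.0


class TestProbeBackmap:
    def _tr_and_genome(self, divergence_positions=()):
        rng = np.random.default_rng(60)
        genome, _ = generate_genome({"chr1": 3000, "chr2": 2000}, seed=60)
        # duplicate chr1[500:700] into chr2 at 800, with optional divergences
        segment = list(genome["chr1"][500:700])
        for off in divergence_positions:
            segment[off] = {"A": "C", "C": "G", "G": "T", "T": "A"}[segment[off]]
        genome["chr2"] = genome["chr2"][:800] + "".join(segment) + genome["chr2"][1000:]
        tr = build_tr_reference(genome, [GenomicInterval("chr1", 450, 750)], spacer_len=50)
        return tr, genome

    def test_unique_probe(self):
        tr, genome = self._tr_and_genome(divergence_positions=None or ())
        # site far from the duplicated segment
        tr2 = build_tr_reference(genome, [GenomicInterval("chr1", 1500, 1800)], spacer_len=50)
        v = VariantCall("TR", 150, tr2.sequence[150], ("A", "C"), "het", 10)
        res = probe_backmap(v, tr2, genome)
        assert res.verdict == "unique" and not res.clipped

    def test_identically_duplicated_probe_is_multi_locus(self):
        tr, genome = self._tr_and_genome()
        v = VariantCall("TR", 150, tr.sequence[150], ("A", "C"), "het", 10)  # genome 600
        assert probe_backmap(v, tr, genome).verdict == "multi_locus"

    def test_probe_clipped_near_block_edge(self):
        tr, genome = self._tr_and_genome()
        v = VariantCall("TR", 5, tr.sequence[5], ("A", "C"), "het", 10)
        assert probe_backmap(v, tr, genome).clipped

    def test_diverged_paralog_defeats_probe_but_not_read_backmapping(self):
        """Probe uniqueness is a weaker screen: with a few divergences the
        51-mer probe maps uniquely (mismatch 0 beats the paralog copy), yet
        individual reads from the paralog still force-map - the read-level
        cleanup is what removes them."""
        tr, genome = self._tr_and_genome(divergence_positions=(40, 90, 160))
        v = VariantCall("TR", 150, tr.sequence[150], ("A", "C"), "het", 10)
        res = probe_backmap(v, tr, genome, probe_max_mismatches=0)
        assert res.verdict == "unique"


class TestEndToEnd:
    def test_paralog_false_positives_eliminated(self, paralog_ts, paralog_run):
        div_sites = paralog_ts.paralog.donor_divergence_sites()
        table = paralog_run.tr_reference.table
        init_sites = {table.tr_to_genome(c.pos) for c in paralog_run.initial_calls}
        fp_init = init_sites & div_sites
        assert len(fp_init) >= 1  # the force-mapping mechanism fires
        final_sites = {(c.ref_name, c.pos) for c in paralog_run.final_calls}
        fp_surviving = final_sites & div_sites
        assert len(fp_surviving) <= 0.05 * len(fp_init)

    def test_planted_snps_retained_with_truth_genotypes(self, paralog_ts, paralog_run):
        truth = paralog_ts.truth_by_site()
        final = {(c.ref_name, c.pos): c.gt_key() for c in paralog_run.final_calls}
        retained = [s for s in truth if s in final]
        assert len(retained) >= 0.95 * len(truth)
        for s in retained:
            assert final[s] == tuple(sorted(truth[s].genotype))

    def test_clean_data_eliminates_nothing(self, clean_run):
        assert clean_run.report.count(VERDICT_ELIMINATED) == 0
        assert all(o.verdict == VERDICT_RETAINED for o in clean_run.report.outcomes)

    def test_monotonicity_final_at_most_initial(self, paralog_run, clean_run, identical_dup_run):
        for run in (paralog_run, clean_run, identical_dup_run):
            assert len(run.final_calls_all) <= len(run.initial_calls)

    def test_final_coordinates_equal_liftover_of_initial(self, paralog_run):
        table = paralog_run.tr_reference.table
        init_lifted = {table.tr_to_genome(c.pos) for c in paralog_run.initial_calls}
        for c in paralog_run.final_calls_all:
            assert (c.ref_name, c.pos) in init_lifted

    def test_identical_duplicate_reads_removed_by_uniqueness(self, identical_dup_ts):
        """Every read simulated from the identically duplicated span has two
        equal-best genome placements, so the uniqueness filter drops it."""
        ts = identical_dup_ts
        donor, dest = ts.paralog.donor, ts.paralog.dest
        aligner = Aligner(ts.genome)
        checked = 0
        for name, origin in ts.read_truth.items():
            if origin.origin != "decoy" or checked >= 10:
                continue
            if origin.errors1:
                continue
            pair = next(p for p in ts.pairs if p.name == name)
            recs = aligner.map_read(pair.seq1, 5)
            if all(dest.start <= r.pos and r.end <= dest.end for r in recs if r.ref_name == dest.chrom) and all(
                origin.frag_start >= dest.start and origin.frag_start + origin.insert_len <= dest.end
                for _ in [0]
            ):
                assert all(r.n_best_hits == 2 for r in recs)
                checked += 1
        assert checked >= 5


def test_run_backmap_soundness_across_seeds():
    """With no paralogy and error-free reads, backmapping never eliminates a
    planted variant, across several generator seeds."""
    from trbackmap.align import remove_duplicates
    from trbackmap.pileup import build_pileups, call_variants
    from trbackmap.intervals import pad_and_merge
    from trbackmap.synth import plant_variants, simulate_reads

    for seed in (1, 2, 3):
        genome, _ = generate_genome({"chr1": 12_000}, seed=seed)
        targets = [GenomicInterval("chr1", 2_000, 4_000), GenomicInterval("chr1", 7_000, 9_000)]
        haps, variants = plant_variants(genome, targets, n_het=6, n_hom=3, seed=seed + 100)
        pairs, _ = simulate_reads(haps, targets, 30, 0, error_rate=0.0, seed=seed + 200)
        merged = pad_and_merge(targets, 49, {c: len(s) for c, s in genome.items()})
        tr = build_tr_reference(genome, merged, spacer_len=50)
        aligner = Aligner(tr.as_mapping())
        records = remove_duplicates(aligner.map_pairs(pairs, 5, (50, 400)))
        mapped = [r for r in records if r.mapped and not r.is_duplicate]
        initial = call_variants(build_pileups(mapped, tr.as_mapping()))
        assert initial  # planted variants were found
        result = run_backmap(records, initial, tr.table, genome, max_mismatches=5)
        assert result.report.count(VERDICT_ELIMINATED) == 0
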