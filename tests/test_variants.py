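"""The filtering and classification cascade on paired tumor/blood calls."""

import itertools

import pytest
from hypothesis import given, settings, strategies as st

from coremut.regions import CorePromoter
from coremut.variants import (ClassifiedMutation, PopulationPanelEntry,
                              VariantCall, VariantError, annotate_novelty,
                              apply_recurrence, build_mutations,
                              classify_origin, classify_repeat_context,
                              classify_type, filter_polymorphisms,
                              find_tandem_repeats, normalize_alleles,
                              round_half_up, summarize)


def mutation(origin="somatic", carriers=("c1", "c2"), ref="A", alt="G",
             pos=100, **kw) -> ClassifiedMutation:
    defaults = dict(gene_id="G1", chrom="chr1", pos=pos, relative_pos=-10,
                    ref=ref, alt=alt, origin=origin,
                    mut_type=classify_type(ref, alt),
                    carriers=frozenset(carriers))
    defaults.update(kw)
    return ClassifiedMutation(**defaults)


class TestNormalization:
    @pytest.mark.parametrize("pos,ref,alt,expected", [
        (10, "A", "G", (10, "A", "G")),
        (10, "AC", "GC", (10, "A", "G")),        # shared suffix
        (10, "CA", "CG", (11, "A", "G")),        # shared prefix, pos shifts
        (10, "CAT", "CGT", (11, "A", "G")),
        (10, "ATG", "A", (10, "ATG", "A")),      # deletion stays anchored
        (10, "A", "AGG", (10, "A", "AGG")),
    ])
    def test_minimal_representation(self, pos, ref, alt, expected):
        assert normalize_alleles(pos, ref, alt) == expected

    def test_identical_alleles_raise(self):
        with pytest.raises(VariantError):
            normalize_alleles(10, "AC", "AC")

    @settings(derandomize=True, max_examples=200)
    @given(st.text(alphabet="ACGT", min_size=1, max_size=6),
           st.text(alphabet="ACGT", min_size=1, max_size=6),
           st.integers(min_value=1, max_value=10_000))
    def test_normalization_is_idempotent_and_keeps_alleles_nonempty(
            self, ref, alt, pos):
        if ref == alt:
            return
        pos2, r2, a2 = normalize_alleles(pos, ref, alt)
        assert r2 and a2 and r2 != a2
        assert pos2 >= pos
        # already-minimal representations are fixed points
        assert normalize_alleles(pos2, r2, a2) == (pos2, r2, a2)
        # length difference (indel size) is preserved
        assert len(r2) - len(a2) == len(ref) - len(alt)

    def test_multiallelic_split_matches_per_allele_expansion(self, toy_promoter, tmp_path):
        """A multi-allelic record yields one call per alt, identical to
        expanding the record naively allele by allele."""
        from coremut.variants import ingest_vcf
        vcf = tmp_path / "t.vcf"
        vcf.write_text(
            "##fileformat=VCFv4.2\n"
            "##contig=<ID=chrT,length=2000>\n"
            "#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\n"
            "chrT\t995\t.\tA\tC,T\t.\tPASS\t.\n")
        calls = ingest_vcf(vcf, "c1", "tumor", [toy_promoter])
        naive = [("chrT", 995, "A", alt) for alt in ("C", "T")]
        assert sorted(c.key for c in calls) == sorted(naive)


class TestIngestBoundaries:
    def _write(self, tmp_path, pos):
        vcf = tmp_path / f"p{pos}.vcf"
        vcf.write_text(
            "##fileformat=VCFv4.2\n##contig=<ID=chrT,length=2000>\n"
            "#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\n"
            f"chrT\t{pos}\t.\tA\tG\t.\tPASS\t.\n")
        return vcf

    @pytest.mark.parametrize("pos,kept", [
        (990, True),    # first window base (tss=1000, up=10)
        (989, False),   # 1 bp upstream of the window
        (1009, True),   # last window base
        (1010, False),  # 1 bp downstream of the window
    ])
    def test_window_restriction(self, toy_promoter, tmp_path, pos, kept):
        from coremut.variants import ingest_vcf
        calls = ingest_vcf(self._write(tmp_path, pos), "c1", "tumor",
                           [toy_promoter])
        assert bool(calls) == kept


class TestOriginClassification:
    def _call(self, case, comp, pos=100):
        return VariantCall("chr1", pos, "A", "G", case, comp)

    def test_tumor_only_is_somatic_across_carriers(self):
        tumor = [self._call(c, "tumor") for c in ("c1", "c2", "c3")]
        blood = [VariantCall("chr1", 200, "C", "T", c, "blood")
                 for c in ("c1", "c2", "c3")]
        origins = classify_origin(tumor, blood)
        for c in ("c1", "c2", "c3"):
            assert origins[c][("chr1", 100, "A", "G")] == "somatic"

    def test_present_in_blood_is_germline(self):
        origins = classify_origin([self._call("c1", "tumor")],
                                  [self._call("c1", "blood")])
        assert origins["c1"][("chr1", 100, "A", "G")] == "germline"

    def test_blood_only_is_germline(self):
        origins = classify_origin([VariantCall("chr1", 5, "A", "G", "c1", "tumor")],
                                  [self._call("c1", "blood")])
        assert origins["c1"][("chr1", 100, "A", "G")] == "germline"

    def test_unpaired_case_excluded_without_manifest(self, caplog):
        import logging
        with caplog.at_level(logging.WARNING):
            origins = classify_origin([self._call("c1", "tumor")], [])
        assert origins == {}
        assert "missing a compartment" in caplog.text

    def test_manifest_pairing_keeps_callless_compartments(self):
        origins = classify_origin([self._call("c1", "tumor")], [],
                                  paired_cases=["c1"])
        assert origins["c1"][("chr1", 100, "A", "G")] == "somatic"

    def test_origin_conflict_resolved_by_majority_tie_germline(self):
        promoter = CorePromoter("G1", "chr1", 120, "+", 50, 50, "A" * 100)
        case_origins = {
            "c1": {("chr1", 100, "A", "G"): "somatic"},
            "c2": {("chr1", 100, "A", "G"): "germline"},
        }
        muts = build_mutations(case_origins, [promoter])
        assert muts[0].origin == "germline"  # tie -> conservative
        case_origins["c3"] = {("chr1", 100, "A", "G"): "somatic"}
        muts = build_mutations(case_origins, [promoter])
        assert muts[0].origin == "somatic"   # 2-1 majority


class TestPolymorphismFilter:
    @pytest.mark.parametrize("maf,kept", [
        (0.05, False),        # common polymorphism removed
        (0.011, False),
        (0.01, True),         # threshold is strict: exactly 0.01 survives
        (0.005, True),
        (None, False),        # presence-only panel entry removes
    ])
    def test_maf_threshold_strict(self, maf, kept):
        m = mutation()
        panel = [PopulationPanelEntry("chr1", 100, "A", "G", maf)]
        survivors = filter_polymorphisms([m], [panel])
        assert (m in survivors) == kept

    def test_absent_from_all_panels_retained(self):
        m = mutation()
        panel = [PopulationPanelEntry("chr1", 999, "A", "G", 0.4)]
        assert filter_polymorphisms([m], [panel]) == [m]
        assert filter_polymorphisms([m], []) == [m]

    def test_adding_panel_entries_never_grows_survivors(self):
        """Monotonicity: each extra panel entry can only shrink the set."""
        muts = [mutation(pos=p) for p in (100, 101, 102)]
        entries = [PopulationPanelEntry("chr1", p, "A", "G", 0.2)
                   for p in (100, 101)]
        sizes = [len(filter_polymorphisms(muts, [entries[:k]]))
                 for k in range(3)]
        assert sizes == sorted(sizes, reverse=True)

    def test_raising_threshold_never_shrinks_survivors(self):
        muts = [mutation(pos=p) for p in (100, 101)]
        panel = [PopulationPanelEntry("chr1", 100, "A", "G", 0.02),
                 PopulationPanelEntry("chr1", 101, "A", "G", 0.2)]
        ns = [len(filter_polymorphisms(muts, [panel], maf_max=t))
              for t in (0.01, 0.05, 0.5)]
        assert ns == sorted(ns)


class TestNovelty:
    def test_novel_iff_absent_everywhere(self):
        m = mutation()
        catalogs = {tag: set() for tag in
                    ("dbsnp", "1000genome", "esp6500", "exac", "gnomad",
                     "cosmic", "clinvar")}
        annotate_novelty([m], catalogs)
        assert m.novel and not m.in_cosmic_analog

    def test_dbsnp_only_not_novel_not_cosmic(self):
        m = mutation()
        annotate_novelty([m], {"dbsnp": {m.key}, "cosmic": set()})
        assert not m.novel and not m.in_cosmic_analog

    def test_cosmic_only_sets_cosmic_flag(self):
        m = mutation()
        annotate_novelty([m], {"cosmic": {m.key}})
        assert not m.novel and m.in_cosmic_analog

    def test_unknown_catalog_tag_rejected(self):
        with pytest.raises(VariantError, match="unknown catalog tag"):
            annotate_novelty([mutation()], {"mydb": set()})


class TestRecurrence:
    @pytest.mark.parametrize("n,kept", [(1, False), (2, True), (77, True)])
    def test_carrier_threshold(self, n, kept):
        m = mutation(carriers=[f"c{i}" for i in range(n)])
        assert (m in apply_recurrence([m])) == kept


class TestTypeClassification:
    @pytest.mark.parametrize("ref,alt,expected", [
        ("A", "G", "substitution"),
        ("AT", "GC", "substitution"),
        ("A", "AG", "insertion"),
        ("C", "CCT", "insertion"),   # CT-track style insertion
        ("ATG", "A", "deletion"),
    ])
    def test_by_allele_lengths(self, ref, alt, expected):
        assert classify_type(ref, alt) == expected

    def test_identical_alleles_error(self):
        with pytest.raises(VariantError):
            classify_type("A", "A")


def brute_force_repeat_overlap(seq: str, lo: int, hi: int) -> bool:
    """Oracle: enumerate every (start, unit) and extend copy by copy."""
    for u in range(1, 7):
        for start in range(len(seq)):
            unit = seq[start:start + u]
            if len(unit) < u:
                break
            copies = 1
            while seq[start + copies * u:start + (copies + 1) * u] == unit:
                copies += 1
            if copies >= 3 and copies * u >= 6:
                if start <= hi + 1 and start + copies * u - 1 >= lo - 1:
                    return True
    return False


class TestRepeatContext:
    def _promoter(self, seq):
        n = len(seq)
        return CorePromoter("G1", "chr1", 1000, "+", n // 2, n - n // 2, seq)

    def test_homopolymer_is_repetitive(self):
        p = self._promoter("ACGATCGGAC" + "TTTTTTTT" + "GACGATCGAC")
        rel = p.index_to_relative(12)
        assert classify_repeat_context(p, rel, 1)

    def test_ct_track_is_repetitive(self):
        p = self._promoter("ACGATCGGAC" + "CTCTCTCTCT" + "GACGATCGAC")
        rel = p.index_to_relative(14)
        assert classify_repeat_context(p, rel, 1)

    def test_non_repetitive_shuffled_sequence(self):
        p = self._promoter("ACGTAGCTAGGATCCATGAC")
        for idx in range(len(p.sequence)):
            assert not classify_repeat_context(p, p.index_to_relative(idx), 1)

    def test_detector_matches_enumeration_oracle(self):
        """Run-based detector agrees with the substring-enumeration oracle
        at every position of seeded random sequences."""
        import numpy as np
        rng = np.random.default_rng(42)
        for _ in range(20):
            seq = "".join(rng.choice(list("ACGT"), size=60))
            p = self._promoter(seq)
            for idx in range(len(seq)):
                rel = p.index_to_relative(idx)
                assert classify_repeat_context(p, rel, 1) == \
                    brute_force_repeat_overlap(seq, idx, idx), (seq, idx)

    def test_run_detection_units(self):
        runs = find_tandem_repeats("AACCTCTCTCTGG")
        assert any(u == 2 for _, _, u in runs)          # CT run found
        assert not find_tandem_repeats("ACGTACGGATCC")  # nothing >= 3 copies


class TestSummarize:
    def test_percentages_match_printed_arithmetic(self):
        """45 substitutions of 69 distinct is 65.2%; 216 occurrences over
        77 cases averages 3 per case."""
        muts = []
        carriers = itertools.count()
        types = ["substitution"] * 45 + ["insertion"] * 10 + ["deletion"] * 14
        extra = [3] * 26 + [0] * 43     # occurrences: 26*5 + 43*2 = 216
        for i, (t, e) in enumerate(zip(types, extra)):
            ref, alt = {"substitution": ("A", "G"), "insertion": ("A", "AG"),
                        "deletion": ("AG", "A")}[t]
            muts.append(mutation(carriers=[f"c{next(carriers)}" for _ in range(2 + e)],
                                 ref=ref, alt=alt, pos=i, gene_id=f"G{i}"))
        s = summarize(muts, n_cases=77)["somatic"]
        assert s["distinct"] == 69
        assert s["total_occurrences"] == 216
        assert s["avg_per_case"] == 3
        assert s["types"]["substitution"]["pct"] == 65.2
        assert s["types"]["insertion"]["pct"] == 14.5
        assert s["types"]["deletion"]["pct"] == 20.3

    def test_percentages_sum_to_100_within_rounding(self):
        muts = [mutation(pos=i, gene_id=f"G{i}",
                         ref="A", alt=["G", "AG", "AGG"][i % 3] if i % 3 else "G")
                for i in range(7)]
        s = summarize(muts, 10)["somatic"]
        total = sum(v["pct"] for v in s["types"].values())
        assert abs(total - 100.0) <= 0.2

    def test_empty_input_gives_zero_table(self):
        s = summarize([], n_cases=77)
        assert s["somatic"]["distinct"] == 0
        assert s["somatic"]["types"]["substitution"]["pct"] == 0.0

    def test_somatic_germline_partition(self):
        muts = [mutation(pos=1), mutation(pos=2, origin="germline")]
        s = summarize(muts, 5)
        assert s["somatic"]["distinct"] + s["germline"]["distinct"] == len(muts)

    def test_rounding_is_half_up(self):
        assert round_half_up(0.25, 1) == 0.3
        assert round_half_up(2.5, 0) == 3.0
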