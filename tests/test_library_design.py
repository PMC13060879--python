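import numpy as np
import pytest

from mprakit.genomic_core import GenomicInterval, fetch_sequence, reverse_complement
from mprakit.library_design import (
    VariantSpec,
    design_saturation,
    design_tiles,
    design_variant_oligos,
    make_scrambles,
    replicate_rule,
)
from mprakit.synthetic_data import make_toy_genome


def brute_force_coverage(oligos, region):
    """Per-base pileup of oligo anchors over a region (independent oracle)."""
    depth = np.zeros(region.length(), dtype=int)
    for o in oligos:
        lo = max(o.anchor.start, region.start) - region.start
        hi = min(o.anchor.end, region.end) - region.start
        depth[lo : hi + 1] += 1
    return depth


class TestDesignTiles:
    def test_single_window_region_two_tiles(self, toy_genome):
        region = GenomicInterval("chrT", 1001, 1270)
        tiles = design_tiles(region, toy_genome)
        assert len(tiles) == 2
        assert {t.anchor.strand for t in tiles} == {"+", "-"}
        plus, minus = sorted(tiles, key=lambda t: t.anchor.strand, reverse=True)
        assert minus.seq == reverse_complement(plus.seq)

    def test_enumerated_windows_450bp(self, toy_genome):
        region = GenomicInterval("chrT", 1001, 1450)
        tiles = design_tiles(region, toy_genome)
        assert len(tiles) == 6  # offsets 0, 90, 180 on each strand
        starts = sorted({t.anchor.start for t in tiles})
        assert starts == [1001, 1091, 1181]

    def test_interior_coverage_matches_pileup_oracle(self, toy_genome):
        region = GenomicInterval("chrT", 2001, 12_000)  # 10 kb
        tiles = design_tiles(region, toy_genome, tile_len=270, step=90)
        depth = brute_force_coverage(tiles, region)
        interior = depth[270:-270]
        assert interior.mean() == 2 * 270 / 90 == 6.0
        assert (interior == 6).all()

    def test_region_shorter_than_tile_rejected(self, toy_genome):
        with pytest.raises(ValueError):
            design_tiles(GenomicInterval("chrT", 1, 100), toy_genome)

    def test_deterministic(self, toy_genome):
        region = GenomicInterval("chrT", 1001, 2000)
        a = design_tiles(region, toy_genome)
        b = design_tiles(region, toy_genome)
        assert a == b


class TestDesignSaturation:
    def test_five_oligos_per_position(self, toy_genome):
        region = GenomicInterval("chrT", 2000, 2099)
        oligos = design_saturation(region, toy_genome)
        assert len(oligos) == 5 * region.length()
        by_class = {}
        for o in oligos:
            by_class[o.allele_class] = by_class.get(o.allele_class, 0) + 1
        assert by_class == {"ref": 100, "snv_alt": 300, "del5": 100}

    def test_alt_set_is_alphabet_complement(self, toy_genome):
        region = GenomicInterval("chrT", 2500, 2500)
        oligos = design_saturation(region, toy_genome)
        ref = next(o for o in oligos if o.allele_class == "ref")
        center = ref.seq[109]
        alts = {o.seq[109] for o in oligos if o.allele_class == "snv_alt"}
        assert alts == set("ACGT") - {center}

    def test_central_base_of_441bp_contig(self):
        rec = make_toy_genome(441, seed=3, contig="c441")
        genome = {rec.id: rec.seq}
        region = GenomicInterval("c441", 221, 221)
        oligos = design_saturation(region, genome, oligo_len=219)
        ref = next(o for o in oligos if o.allele_class == "ref")
        assert ref.seq == rec.seq[111:330]  # 1-based 112..330
        dele = next(o for o in oligos if o.allele_class == "del5")
        assert len(dele.seq) == 214

    def test_snv_alt_differs_at_exactly_center(self, toy_genome):
        region = GenomicInterval("chrT", 3000, 3004)
        oligos = design_saturation(region, toy_genome)
        refs = {o.focal_pos: o for o in oligos if o.allele_class == "ref"}
        for o in oligos:
            if o.allele_class != "snv_alt":
                continue
            ref = refs[o.focal_pos]
            diffs = [i for i, (a, b) in enumerate(zip(ref.seq, o.seq)) if a != b]
            assert diffs == [109]

    def test_del5_is_ref_with_centered_gap(self, toy_genome):
        region = GenomicInterval("chrT", 3000, 3004)
        oligos = design_saturation(region, toy_genome)
        refs = {o.focal_pos: o for o in oligos if o.allele_class == "ref"}
        for o in oligos:
            if o.allele_class != "del5":
                continue
            ref = refs[o.focal_pos].seq
            assert o.seq == ref[:107] + ref[112:]  # focal +/- 2 removed

    def test_edge_positions_skipped_not_shifted(self, toy_genome):
        region = GenomicInterval("chrT", 1, 150)  # windows leave the contig
        oligos = design_saturation(region, toy_genome)
        designed_positions = {o.focal_pos for o in oligos}
        assert designed_positions == set(range(110, 151))

    def test_even_oligo_length_rejected(self, toy_genome):
        with pytest.raises(ValueError):
            design_saturation(GenomicInterval("chrT", 2000, 2001), toy_genome, oligo_len=218)


class TestDesignVariantOligos:
    def snv(self, genome, pos=5000):
        ref = genome["chrT"][pos - 1]
        alt = next(b for b in "ACGT" if b != ref)
        return VariantSpec("chrT", pos, ref, alt, allele_count=5, allele_frequency=0.01)

    def deletion(self, genome, pos=5000, k=2):
        ref = genome["chrT"][pos - 1 : pos + k]
        return VariantSpec("chrT", pos, ref, ref[0], allele_count=5, allele_frequency=0.01)

    def insertion(self, genome, pos=5000, k=2):
        anchor = genome["chrT"][pos - 1]
        return VariantSpec("chrT", pos, anchor, anchor + "A" * k, allele_count=5,
                           allele_frequency=0.01)

    def test_snv_pair_lengths_and_hamming(self, toy_genome):
        res = design_variant_oligos([self.snv(toy_genome)], toy_genome)
        (ref, alt), = res.pairs
        assert len(ref.seq) == len(alt.seq) == 219
        diffs = [i for i, (a, b) in enumerate(zip(ref.seq, alt.seq)) if a != b]
        assert diffs == [109]  # centered

    @pytest.mark.parametrize("k,ref_len", [(1, 219), (2, 218), (3, 219), (4, 218)])
    def test_deletion_parity_rule(self, toy_genome, k, ref_len):
        res = design_variant_oligos([self.deletion(toy_genome, k=k)], toy_genome)
        (ref, alt), = res.pairs
        assert len(ref.seq) == ref_len
        assert len(alt.seq) == ref_len - k
        # alt aligns to ref with a single centered k-base gap
        flank = (ref_len - k) // 2
        assert alt.seq == ref.seq[:flank] + ref.seq[flank + k :]

    @pytest.mark.parametrize("k,alt_len", [(1, 219), (2, 218), (3, 219)])
    def test_insertion_parity_mirrors_deletion(self, toy_genome, k, alt_len):
        res = design_variant_oligos([self.insertion(toy_genome, k=k)], toy_genome)
        (ref, alt), = res.pairs
        assert len(alt.seq) == alt_len
        assert len(ref.seq) == alt_len - k
        flank = (alt_len - k) // 2
        assert alt.seq[:flank] == ref.seq[:flank]
        assert alt.seq[flank + k :] == ref.seq[flank:]
        assert alt.seq[flank : flank + k] == "A" * k

    def test_oversize_indel_rejected(self, toy_genome):
        v = self.deletion(toy_genome, k=11)
        res = design_variant_oligos([v], toy_genome)
        assert res.pairs == []
        assert res.rejected == [(v, "indel_gt_10")]

    def test_zero_allele_count_rejected(self, toy_genome):
        v = VariantSpec("chrT", 5000, toy_genome["chrT"][4999],
                        next(b for b in "ACGT" if b != toy_genome["chrT"][4999]),
                        allele_count=0)
        res = design_variant_oligos([v], toy_genome)
        assert res.rejected == [(v, "ac_zero")]

    def test_ref_oligo_matches_genome(self, toy_genome):
        res = design_variant_oligos([self.snv(toy_genome)], toy_genome)
        (ref, _), = res.pairs
        assert ref.seq == fetch_sequence(toy_genome, ref.anchor).seq


class TestReplicateRule:
    def make_variants(self, genome, freqs):
        out = []
        for i, f in enumerate(freqs):
            pos = 5000 + i * 300
            ref = genome["chrT"][pos - 1]
            alt = next(b for b in "ACGT" if b != ref)
            out.append(VariantSpec("chrT", pos, ref, alt, allele_count=5, allele_frequency=f))
        return out

    def test_duplication_threshold(self, toy_genome):
        variants = self.make_variants(toy_genome, [1.0, 0.5])
        design = design_variant_oligos(variants, toy_genome)
        oligos = replicate_rule(design, variants)
        per_key = {}
        for o in oligos:
            per_key[o.variant_key] = per_key.get(o.variant_key, 0) + 1
        assert per_key[variants[0].key] == 4  # 2 copies x (ref, alt)
        assert per_key[variants[1].key] == 2
        assert len({o.oligo_id for o in oligos}) == len(oligos)  # distinct ids

    def test_pair_count_enumeration(self, toy_genome):
        variants = self.make_variants(toy_genome, [1.0, 1.5, 2.0, 0.5, 0.9])
        design = design_variant_oligos(variants, toy_genome)
        oligos = replicate_rule(design, variants)
        assert len(oligos) == (3 * 2 + 2) * 2  # 8 ref/alt pairs


class TestMakeScrambles:
    def sources(self, toy_genome, n=6):
        region = GenomicInterval("chrT", 2000, 2000 + n - 1)
        return [o for o in design_saturation(region, toy_genome) if o.allele_class == "ref"]

    def test_composition_preserved(self, toy_genome):
        sources = self.sources(toy_genome)
        for s in make_scrambles(sources, n=4, rng_seed=1):
            src = next(o for o in sources if o.oligo_id in s.oligo_id)
            assert sorted(s.seq) == sorted(src.seq)

    def test_deterministic(self, toy_genome):
        sources = self.sources(toy_genome)
        a = make_scrambles(sources, n=4, rng_seed=7)
        b = make_scrambles(sources, n=4, rng_seed=7)
        assert a == b

    def test_length_cover(self, toy_genome):
        region = GenomicInterval("chrT", 2000, 2005)
        sat = design_saturation(region, toy_genome)
        sources = [o for o in sat if o.allele_class in ("ref", "del5")]  # 219 and 214
        scrambles = make_scrambles(sources, n=3, rng_seed=0)
        assert {len(s.seq) for s in scrambles} == {219, 214}

    def test_center_substituted_siblings(self, toy_genome):
        sources = self.sources(toy_genome)
        out = make_scrambles(sources, n=2, rng_seed=0, with_center_substitutions=True)
        assert len(out) == 2 * 4  # each scramble plus 3 center-substituted siblings

    def test_too_many_requested(self, toy_genome):
        with pytest.raises(ValueError):
            make_scrambles(self.sources(toy_genome), n=99, rng_seed=0)
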