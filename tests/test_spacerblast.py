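import numpy as np
import pytest

from spacerphy import CRISPRArray, find_protospacers, summarize_targets
from spacerphy.arrays import SpacerCatalog, reverse_complement
from spacerphy.spacerblast import (
    ProtospacerHit,
    read_bed_mask,
    write_hits_tsv,
)

from helpers import naive_protospacer_scan, random_dna


def plant(subject, pos, insert):
    return subject[:pos] + insert + subject[pos + len(insert):]


class TestFindProtospacers:
    def test_forward_hit_with_5prime_cc_pam(self, rng):
        spacer = random_dna(rng, 20)
        subject = plant(random_dna(rng, 200), 50, "CC" + spacer)
        hits = find_protospacers(SpacerCatalog({"s1": spacer}),
                                 {"c": subject})
        [h] = [h for h in hits if h.strand == "+"] or hits
        assert (h.start, h.end, h.strand) == (52, 72, "+")
        assert h.pam_observed == "CC" and h.pam_pass is True
        assert h.percent_identity == 100.0

    def test_reverse_hit_reads_pam_on_protospacer_strand(self, rng):
        spacer = random_dna(rng, 20)
        # GG immediately 3' on the forward strand == CC 5' on the minus
        # strand where the protospacer sits
        subject = plant(random_dna(rng, 200), 100,
                        reverse_complement(spacer) + "GG")
        hits = find_protospacers(SpacerCatalog({"s1": spacer}),
                                 {"c": subject})
        minus = [h for h in hits if h.strand == "-"]
        assert len(minus) == 1
        assert minus[0].pam_observed == "CC" and minus[0].pam_pass is True

    def test_hit_inside_masked_interval_dropped(self, rng):
        spacer = random_dna(rng, 20)
        subject = plant(random_dna(rng, 200), 50, spacer)
        cat = SpacerCatalog({"s1": spacer})
        unmasked = find_protospacers(cat, {"c": subject})
        masked = find_protospacers(cat, {"c": subject},
                                   mask={"c": [(40, 80)]})
        assert len(unmasked) >= 1 and masked == []
        # one-base overlap is enough to drop the hit
        edge = find_protospacers(cat, {"c": subject}, mask={"c": [(69, 75)]})
        assert edge == []
        clear = find_protospacers(cat, {"c": subject}, mask={"c": [(70, 75)]})
        assert len(clear) == len(unmasked)

    def test_lowering_identity_never_removes_hits(self, rng):
        spacer = random_dna(rng, 24)
        subject = random_dna(rng, 3000)
        subject = plant(subject, 100, spacer)
        mutated = list(spacer)
        mutated[5] = {"A": "C", "C": "A", "G": "T", "T": "G"}[mutated[5]]
        subject = plant(subject, 500, "".join(mutated))
        cat = SpacerCatalog({"s1": spacer})
        prev = set()
        for ident in (100.0, 95.0, 90.0, 80.0):
            hits = {(h.start, h.end, h.strand)
                    for h in find_protospacers(cat, {"c": subject},
                                               min_identity=ident)}
            assert prev <= hits
            prev = hits

    def test_mismatches_counted_over_full_length_off_contig(self, rng):
        spacer = random_dna(rng, 20)
        # only the last 15 bases fit on the contig start
        subject = spacer[5:] + random_dna(rng, 100)
        hits = find_protospacers(SpacerCatalog({"s1": spacer}),
                                 {"c": subject}, min_identity=75.0)
        edge_hits = [h for h in hits if h.start == -5]
        assert len(edge_hits) == 1
        assert edge_hits[0].mismatches == 5
        assert edge_hits[0].pam_pass is None  # flank unreachable

    @pytest.mark.parametrize("pattern", ["CN", "YG", "NN"])
    def test_iupac_patterns_accepted(self, rng, pattern):
        spacer = random_dna(rng, 20)
        subject = plant(random_dna(rng, 100), 30, "CC" + spacer)
        hits = find_protospacers(SpacerCatalog({"s": spacer}),
                                 {"c": subject}, pam=pattern)
        assert any(h.pam_pass is not None for h in hits)

    def test_unknown_iupac_symbol_rejected(self):
        with pytest.raises(ValueError, match="IUPAC"):
            find_protospacers(SpacerCatalog({"s": "ACGT"}), {"c": "ACGT"},
                              pam="CX")

    def test_malformed_mask_interval_rejected(self):
        with pytest.raises(ValueError, match="interval"):
            find_protospacers(SpacerCatalog({"s": "ACGTACGT"}),
                              {"c": "ACGTACGT"}, mask={"c": [(5, 2)]})

    def test_matches_naive_scan_oracle(self, rng):
        subject = random_dna(rng, 10_000)
        spacers = {}
        planted = []
        for i in range(6):
            sp = random_dna(rng, 22)
            spacers[f"p{i}"] = sp
            pos = 300 + i * 1500
            insert = sp if i % 2 == 0 else reverse_complement(sp)
            if i >= 4:  # two planted with one mismatch
                chars = list(insert)
                chars[7] = {"A": "C", "C": "A", "G": "T",
                            "T": "G"}[chars[7]]
                insert = "".join(chars)
            subject = plant(subject, pos, insert)
            planted.append(pos)
        cat = SpacerCatalog(spacers)
        mask = {"c": [(2000, 2100)]}
        for ident in (100.0, 90.0):
            got = {(h.spacer_id, h.start, h.end, h.strand, h.mismatches)
                   for h in find_protospacers(cat, {"c": subject},
                                              min_identity=ident,
                                              mask=mask)}
            expected = set()
            for sid, sp in spacers.items():
                max_mm = int(len(sp) * (100 - ident) / 100)
                expected |= set(naive_protospacer_scan(
                    subject, sid, sp, max_mm, mask["c"]))
            assert got == expected


class TestSummarizeTargets:
    def _hit(self, sid, subject, start=0, pam=True):
        return ProtospacerHit(sid, subject, start, start + 20, "+",
                              100.0, 0, "CC", pam)

    def test_counts_distinct_subjects(self):
        hits = [self._hit("s1", "g1"), self._hit("s1", "g2"),
                self._hit("s1", "g3"), self._hit("s2", "g1", 10),
                self._hit("s2", "g1", 50)]
        counts = summarize_targets(hits)
        assert counts == {"s1": 3, "s2": 1}

    def test_counts_match_brute_force_group_by(self, rng):
        hits = [self._hit(f"s{rng.integers(4)}", f"g{rng.integers(6)}",
                          int(rng.integers(100)))
                for _ in range(60)]
        counts = summarize_targets(hits)
        brute = {}
        for h in hits:
            brute.setdefault(h.spacer_id, set()).add(h.subject_id)
        assert counts == {k: len(v) for k, v in brute.items()}

    def test_arrays_backfill_zero_counts(self):
        hits = [self._hit("s1", "g1")]
        counts = summarize_targets(
            hits, arrays=[CRISPRArray("A", ("s1", "s9"))])
        assert counts["s9"] == 0


class TestIO:
    def test_bed_mask_parsing(self, tmp_path):
        p = tmp_path / "m.bed"
        p.write_text("c1\t100\t200\nc1\t500\t600\nc2\t0\t50\n")
        mask = read_bed_mask(p)
        assert mask == {"c1": [(100, 200), (500, 600)], "c2": [(0, 50)]}

    def test_bed_malformed_interval_rejected(self, tmp_path):
        p = tmp_path / "m.bed"
        p.write_text("c1\t200\tnope\n")
        with pytest.raises(ValueError, match="malformed"):
            read_bed_mask(p)

    def test_hits_tsv_has_header_and_rows(self, tmp_path, rng):
        spacer = random_dna(rng, 20)
        subject = plant(random_dna(rng, 100), 40, spacer)
        hits = find_protospacers(SpacerCatalog({"s1": spacer}),
                                 {"c": subject})
        out = tmp_path / "hits.tsv"
        write_hits_tsv(hits, out)
        lines = out.read_text().strip().split("\n")
        assert lines[0].startswith("spacer_id\t")
        assert len(lines) == len(hits) + 1
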