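import math

import numpy as np
import pytest

import modumap as mm

from conftest import random_protein

MODULE_15 = mm.ProteinSequence("bendo-n", "YGGFMTSEKSQTPLV")


def embedded_receptor(region="EC2", divergence=0.0, seed=0, offset=0):
    rec, topo = mm.generate_receptor(mm.SyntheticSpec(seed=seed))
    emb, span = mm.embed_module(rec, topo, mm.EmbedSpec(
        module=MODULE_15, region=region, offset=offset,
        divergence=divergence, seed=seed + 1))
    return emb, topo, span


class TestScanPeptides:
    def test_verbatim_module_yields_passing_hit_in_region(self):
        receptor, topo, span = embedded_receptor("EC2")
        hits = mm.scan_peptides([MODULE_15], receptor, topo)
        passing = [h for h in hits if h.passes]
        assert passing
        top = passing[0]
        assert top.we_score >= 35
        assert dict(top.regions).get("EC2", 0) >= 10
        s = top.alignment.target_span
        assert s[0] <= span[1] and s[1] >= span[0]

    def test_random_peptide_rarely_hits(self):
        rng = np.random.default_rng(19)
        peptide = random_protein(rng, 30, "p")
        receptor, _ = mm.generate_receptor(mm.SyntheticSpec(seed=77))
        hits = mm.scan_peptides([peptide], receptor)
        assert not any(h.passes for h in hits)

    def test_order_invariance(self):
        receptor, topo, _ = embedded_receptor("TM5")
        rng = np.random.default_rng(20)
        other = random_protein(rng, 25, "other")
        fwd = mm.scan_peptides([MODULE_15, other], receptor, topo)
        rev = mm.scan_peptides([other, MODULE_15], receptor, topo)
        key = lambda h: (h.peptide_id, h.we_score,
                         h.alignment.query_span, h.alignment.target_span)
        assert sorted(map(key, fwd)) == sorted(map(key, rev))

    def test_passing_hits_satisfy_we_threshold(self):
        receptor, topo, _ = embedded_receptor("EC3", divergence=0.1)
        hits = mm.scan_peptides([MODULE_15], receptor, topo)
        for h in hits:
            if h.passes:
                assert h.we_score >= 35

    def test_evalue_attached_when_shuffling_enabled(self):
        receptor, topo, _ = embedded_receptor("EC2")
        hits = mm.scan_peptides([MODULE_15], receptor, topo, n_shuffles=120,
                                seed=4)
        top = hits[0]
        assert not math.isnan(top.evalue)
        assert top.evalue < 0.05  # a planted 15-mer is far in the null tail
        again = mm.scan_peptides([MODULE_15], receptor, topo, n_shuffles=120,
                                 seed=4)
        assert again[0].evalue == top.evalue

    def test_topology_id_mismatch_rejected(self):
        receptor, _, _ = embedded_receptor()
        _, wrong_topo = mm.generate_receptor(mm.SyntheticSpec(seed=5),
                                             seq_id="someone-else")
        with pytest.raises(ValueError, match="topology"):
            mm.scan_peptides([MODULE_15], receptor, wrong_topo)

    def test_empty_peptides_rejected(self):
        receptor, _, _ = embedded_receptor()
        with pytest.raises(ValueError):
            mm.scan_peptides([], receptor)


class TestMapHitToRegions:
    @staticmethod
    def hit_with_span(span, topo, local_params):
        n = span[1] - span[0] + 1
        residues = "W" * n
        cols = tuple(zip(residues, residues))
        from modumap.align import score_columns
        aln = mm.PairwiseAlignment(
            query_id="q", target_id=topo.sequence_id, columns=cols,
            score=score_columns(cols, local_params, mm.Mode.LOCAL),
            mode=mm.Mode.LOCAL, query_span=(1, n), target_span=span,
            params=local_params)
        return mm.HomologyHit("q", topo.sequence_id, aln, aln.score,
                              math.nan, True, ())

    @pytest.fixture()
    def toy_topology(self):
        # EC1 = 1..50, TM1 = 51..73, rest one residue each
        lengths = {lbl: 1 for lbl in mm.REGION_LABELS}
        lengths["EC1"], lengths["TM1"] = 50, 23
        segments = []
        pos = 1
        for lbl in mm.REGION_LABELS:
            segments.append((lbl, pos, pos + lengths[lbl] - 1))
            pos += lengths[lbl]
        return mm.TopologyAnnotation("t", tuple(segments))

    def test_span_inside_one_region(self, toy_topology, local_params):
        hit = self.hit_with_span((10, 20), toy_topology, local_params)
        assert mm.map_hit_to_regions(hit, toy_topology) == [("EC1", 11)]

    def test_span_across_boundary(self, toy_topology, local_params):
        hit = self.hit_with_span((48, 55), toy_topology, local_params)
        assert mm.map_hit_to_regions(hit, toy_topology) == [("EC1", 3),
                                                            ("TM1", 5)]

    def test_min_overlap_suppresses_spillover(self, toy_topology,
                                              local_params):
        hit = self.hit_with_span((48, 52), toy_topology, local_params)
        assert mm.map_hit_to_regions(hit, toy_topology, min_overlap=3) == \
            [("EC1", 3)]

    def test_overlaps_sum_to_span_length_at_min_overlap_one(self,
                                                            local_params):
        _, topo = mm.generate_receptor(mm.SyntheticSpec(seed=30))
        rng = np.random.default_rng(22)
        for _ in range(20):
            lo = int(rng.integers(1, topo.length - 30))
            hi = lo + int(rng.integers(0, 30))
            hit = self.hit_with_span((lo, hi), topo, local_params)
            overlaps = mm.map_hit_to_regions(hit, topo, min_overlap=1)
            assert sum(o for _, o in overlaps) == hi - lo + 1

    def test_span_outside_sequence_rejected(self, toy_topology,
                                            local_params):
        hit = self.hit_with_span((80, 100), toy_topology, local_params)
        with pytest.raises(ValueError, match="outside"):
            mm.map_hit_to_regions(hit, toy_topology)


class TestArchitectureSummary:
    def test_flags_exactly_where_modules_sit(self):
        rec, topo = mm.generate_receptor(mm.SyntheticSpec(seed=55))
        step1, _ = mm.embed_module(rec, topo, mm.EmbedSpec(
            module=MODULE_15, region="EC1", divergence=0.0))
        step2, _ = mm.embed_module(step1, topo, mm.EmbedSpec(
            module=MODULE_15, region="IC4", divergence=0.0))
        hits = mm.scan_peptides([MODULE_15], step2, topo)
        summary = mm.architecture_summary(hits, topo)
        flagged = {r for r, present in summary.module_present.items() if present}
        assert flagged == {"EC1", "IC4"}

    def test_no_passing_hits_means_no_flags(self):
        rng = np.random.default_rng(23)
        rec, topo = mm.generate_receptor(mm.SyntheticSpec(seed=56))
        hits = mm.scan_peptides([random_protein(rng, 20, "p")], rec, topo)
        summary = mm.architecture_summary(hits, topo)
        assert not any(summary.module_present.values())

    def test_contrasting_receptors_differ_in_module_regions(self):
        """Receptors with modules in different regions summarize differently."""
        recA, topoA = mm.generate_receptor(mm.SyntheticSpec(seed=60),
                                           seq_id="opioid-like")
        recB, topoB = mm.generate_receptor(mm.SyntheticSpec(seed=61),
                                           seq_id="adrenergic-like")
        embA, _ = mm.embed_module(recA, topoA, mm.EmbedSpec(
            module=MODULE_15, region="EC1", divergence=0.0))
        embB, _ = mm.embed_module(recB, topoB, mm.EmbedSpec(
            module=MODULE_15, region="IC3", divergence=0.0))
        sumA = mm.architecture_summary(
            mm.scan_peptides([MODULE_15], embA, topoA), topoA)
        sumB = mm.architecture_summary(
            mm.scan_peptides([MODULE_15], embB, topoB), topoB)
        onlyA = {r for r, p in sumA.module_present.items()
                 if p and not sumB.module_present[r]}
        onlyB = {r for r, p in sumB.module_present.items()
                 if p and not sumA.module_present[r]}
        assert "EC1" in onlyA
        assert "IC3" in onlyB

    def test_conservation_classes_joined(self, global_params):
        rec, topo = mm.generate_receptor(mm.SyntheticSpec(seed=62))
        aln = mm.global_align_free_ends(rec, rec, global_params)
        summary = mm.average_conservation(
            mm.region_conservation(aln, topo, pair_id="self"))
        emb, _ = mm.embed_module(rec, topo, mm.EmbedSpec(
            module=MODULE_15, region="EC2", divergence=0.0))
        hits = mm.scan_peptides([MODULE_15], emb, topo)
        arch = mm.architecture_summary(hits, topo, summary)
        assert arch.conservation_class["EC2"] == "high"


class TestPresets:
    def test_peptide_scan_preset(self):
        p = mm.preset_params("peptide-scan")
        assert (p.matrix.name, p.gap_open, p.gap_extend, p.mode) == \
            ("BLOSUM80", -10, -2, mm.Mode.LOCAL)

    def test_receptor_compare_preset(self):
        p = mm.preset_params("receptor-compare")
        assert (p.matrix.name, p.gap_open, p.gap_extend, p.mode) == \
            ("BLOSUM80", -12, -2, mm.Mode.GLOBAL_FREE_ENDS)

    def test_unknown_preset(self):
        with pytest.raises(ValueError):
            mm.preset_params("blast-defaults")
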