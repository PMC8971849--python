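"""Deduplication, model extension, the refinement loop, motif tallies
and the structured report."""

import copy
import math

import numpy as np
import pytest

from intronscan.model import StructuredAlignment
from intronscan.profiles import train, tstat
from intronscan.search import Hit, search, single_level_strategy
from intronscan.synth import FixtureSpec, implant, make_model
from intronscan.weasel import (dedupe, extend_model, iterate, p_distance,
                               parse_report, render_motif, render_report,
                               tally_motifs)
from conftest import small_spec
from oracle import single_linkage_clusters


def _hit(seqs, ev=1e-9, start=1, contig="c", model="m"):
    """Hit carrying only element sequences (enough for dedupe)."""
    end = start + 50
    return Hit(model, contig, "+", start, end, 10.0, ev,
               {}, (), dict(enumerate(seqs, 1)), {})


class TestDedupe:
    def test_identical_sequences_collapse(self):
        h1 = _hit(["ACGUACGU"], ev=1e-9, start=1)
        h2 = _hit(["ACGUACGU"], ev=1e-6, start=100)
        kept = dedupe([h1, h2], identity_threshold=0.02)
        assert kept == [h1]

    def test_distant_sequences_all_retained(self):
        hits = [_hit(["AAAAAAAA"]), _hit(["GGGGCCCC"]), _hit(["UUUUGGGG"])]
        kept = dedupe(hits, identity_threshold=0.10)
        assert len(kept) == 3

    @pytest.mark.parametrize("seed", range(5))
    def test_matches_bruteforce_single_linkage(self, seed):
        rng = np.random.default_rng(seed)
        base = "".join("ACGU"[b] for b in rng.integers(0, 4, 30))
        seqs = []
        for _ in range(12):
            s = list(base)
            for pos in rng.choice(30, size=rng.integers(0, 12),
                                  replace=False):
                s[pos] = "ACGU"[rng.integers(0, 4)]
            seqs.append("".join(s))
        hits = [_hit([s], ev=10.0 ** -rng.integers(3, 12), start=i * 60 + 1)
                for i, s in enumerate(seqs)]
        kept = dedupe(hits, identity_threshold=0.15)
        clusters = single_linkage_clusters(seqs, 0.15)
        assert len(kept) == len(clusters)
        # exactly one representative kept per cluster, the best-E one
        for cl in clusters:
            members = [hits[i] for i in cl]
            reps = [h for h in kept if h in members]
            assert len(reps) == 1
            assert reps[0].evalue == min(h.evalue for h in members)

    def test_jukes_cantor_option(self):
        assert p_distance("AAAA", "AAAC") == pytest.approx(0.25)
        jc = p_distance("AAAA", "AAAC", jukes_cantor=True)
        assert jc == pytest.approx(-0.75 * math.log(1 - 4 * 0.25 / 3))


class TestExtendModel:
    def _search_fixture(self, n_implants=6, seed=31, bg=12_000):
        # moderate conservation so sampled introns differ from the
        # training rows (byte-identical hits are correctly dropped)
        spec = small_spec(seed, background_length=bg, conservation=0.85)
        model, pset = make_model(spec)
        ts = tstat(pset, model)
        strat = single_level_strategy(model, ts)
        genomes, truth = implant([(model, spec)], {model.name: n_implants},
                                 seed=seed + 1, background_length=bg)
        hits = search(model, pset, strat, genomes)
        return spec, model, pset, genomes, hits

    def test_extension_preserves_invariants(self):
        spec, model, pset, genomes, hits = self._search_fixture()
        assert len(hits) >= 3
        extended, n_added = extend_model(model, hits, pset=pset,
                                        identity_threshold=0.02)
        assert n_added >= 1
        assert extended.n_sequences == model.n_sequences + n_added
        # re-parses as a valid model with the same element topology
        assert [
            (e.element_id, e.kind, e.pseudoknot) for e in extended.elements
        ] == [(e.element_id, e.kind, e.pseudoknot) for e in model.elements]
        # observed spacer bounds stay consistent
        for r in extended.variable_regions:
            assert r.min_len <= r.max_len <= r.columns[1] - r.columns[0]

    def test_rows_added_verbatim_under_element_columns(self):
        spec, model, pset, genomes, hits = self._search_fixture()
        extended, n_added = extend_model(model, hits, pset=pset,
                                        identity_threshold=0.02)
        new_rows = dict(extended.sequences[model.n_sequences:])
        by_key = {f"{h.contig}_{h.start}_{h.end}{h.strand}": h for h in hits}
        for rid, row in new_rows.items():
            h = by_key[rid]
            for e in extended.elements:
                seq = h.element_seqs[e.element_id]
                if isinstance(seq, tuple):
                    assert row[slice(*e.columns5)] == seq[0]
                    assert row[slice(*e.columns3)] == seq[1]

    def test_partial_hits_rejected_with_warning(self, fixture_model):
        spec, model, pset = fixture_model
        bad = Hit(model.name, "c", "+", 1, 40, 5.0, 1e-9, {}, (),
                  {1: "AAAA"}, {})
        warnings = []
        extended, n = extend_model(model, [bad], pset=pset,
                                   on_warning=warnings.append)
        assert n == 0 and extended is model
        assert any("misses elements" in w for w in warnings)

    def test_variable_region_widened_for_long_spacer(self):
        spec, model, pset, genomes, hits = self._search_fixture()
        h = hits[0]
        ridx = max(h.region_seqs, key=lambda r: len(h.region_seqs[r]))
        long_spacer = h.region_seqs[ridx] + "ACGUACGU"
        h.region_seqs[ridx] = long_spacer
        extended, n_added = extend_model(model, [h], pset=pset,
                                        identity_threshold=0.02)
        assert n_added == 1
        r = next(r for r in extended.variable_regions if r.index == ridx)
        assert r.columns[1] - r.columns[0] >= len(long_spacer)
        assert r.max_len == len(long_spacer)


class TestIterate:
    def test_round_log_and_fixed_point(self):
        spec = small_spec(41, background_length=9000, conservation=0.95)
        model, pset = make_model(spec)
        genomes, truth = implant([(model, spec)], {model.name: 5}, seed=42,
                                 background_length=9000)
        m1, log1 = iterate(model, genomes, rounds=4, seed=5,
                           n_shuffles=40, shuffle_len=1000)
        assert log1[0].n_hits >= 4
        assert log1[-1].n_added == 0 or len(log1) == 4
        # re-running on the converged output is a fixed point
        m2, log2 = iterate(m1, genomes, rounds=3, seed=5,
                           n_shuffles=40, shuffle_len=1000)
        assert m2.sequences == m1.sequences
        assert log2[0].n_added == 0


class TestMotifTally:
    def _hits_with_motifs(self, model, motifs):
        """Hits whose helix-2 sequences spell the given 5' motifs."""
        hits = []
        e2 = model.element(2)
        for i, m5 in enumerate(motifs):
            comp = {"A": "U", "U": "A", "G": "C", "C": "G"}
            m3 = "".join(comp[c] for c in reversed(m5))
            hits.append(Hit(model.name, "c", "+", i * 100 + 1, i * 100 + 60,
                            20.0, 1e-8, {}, (), {1: "AAAA", 2: (m5, m3),
                                                 3: "GGGG"}, {}))
        return hits

    def test_counts_order_and_min_count_filter(self, toy_model):
        motifs = ["GGC"] * 12 + ["GAC"] * 5 + ["CCC"] * 4
        hits = self._hits_with_motifs(toy_model, motifs)
        tally = tally_motifs(toy_model, hits, 2, min_count=5)
        assert tally.total == 21
        assert [c for _, c in tally.variants] == [12, 5]
        assert tally.predominant.startswith("GGC")
        # the 4-copy variant is dropped by the threshold
        assert all(not m.startswith("CCC") for m, _ in tally.variants)

    def test_difference_positions_vs_predominant(self, toy_model):
        motifs = ["GGC"] * 7 + ["GAC"] * 5
        hits = self._hits_with_motifs(toy_model, motifs)
        tally = tally_motifs(toy_model, hits, 2, min_count=5)
        variant = next(m for m, _ in tally.variants if m != tally.predominant)
        diffs = tally.differences[variant]
        assert diffs is not None and len(diffs) > 0
        for i in diffs:
            assert variant[i] != tally.predominant[i]

    def test_single_motif_counts_all_hits(self, toy_model):
        hits = self._hits_with_motifs(toy_model, ["GGC"] * 6)
        tally = tally_motifs(toy_model, hits, 2, min_count=5)
        assert tally.variants == [(tally.predominant, 6)]
        assert sum(c for _, c in tally.variants) == tally.total

    def test_bulge_rendering_between_helix_blocks(self):
        """A single strand directly between two helix strands renders
        between underscores (helix-bulge-helix motif)."""
        # helix 2 - bulge 3 - helix 4 ... helix 4' - helix 2'
        tokens = "2 3 4 4 . . 4 4 2".split()
        rows = [("a", "CAGAUUUCG"), ("b", "CAGAAAUCG")]
        m = StructuredAlignment.from_sequences("p7", rows, tokens)
        hit = Hit("p7", "c", "+", 1, 9, 5.0, 1e-6, {}, (),
                  {2: ("C", "G"), 3: "A", 4: ("GA", "UC")}, {})
        motif = render_motif(m, hit, (2, 3, 4))
        assert motif == "C_A_GA...UCG"


class TestReport:
    def test_report_round_trips_hit_coordinates(self):
        spec = small_spec(51, background_length=8000)
        model, pset = make_model(spec)
        ts = tstat(pset, model)
        strat = single_level_strategy(model, ts)
        genomes, _ = implant([(model, spec)], {model.name: 4}, seed=52,
                             background_length=8000)
        from intronscan.search import calibrate_evalues
        calib = calibrate_evalues(model, pset, strat, n_shuffles=40,
                                  shuffle_len=1000, seed=1)
        hits = search(model, pset, strat, genomes, calib)
        assert len(hits) >= 3
        text = render_report(model, hits)
        parsed = parse_report(text)
        assert [(p["contig"], p["strand"], p["start"], p["end"])
                for p in parsed] == \
            [(h.contig, h.strand, h.start, h.end) for h in hits]
        for p, h in zip(parsed, hits):
            assert p["score"] == pytest.approx(h.score, abs=5e-5)
            assert p["evalue"] == pytest.approx(h.evalue, rel=1e-2)
        # E-values ascend; uppercase only inside element blocks
        evs = [p["evalue"] for p in parsed]
        assert evs == sorted(evs)
        for line in text.splitlines():
            if line.startswith(("#", ">")):
                continue
            blocks = [tok for tok in line.split() if not tok.isdigit()]
            assert all(tok.isupper() for tok in blocks)
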