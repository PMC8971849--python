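"""Multi-level search: planted identities, strand symmetry, exact
agreement with exhaustive placement enumeration, pruning monotonicity and
the Gumbel E-value model."""

import math

import numpy as np
import pytest

from intronscan.alphabet import revcomp_dna, to_dna
from intronscan.model import GenomeRecord
from intronscan.profiles import tstat, train
from intronscan.search import (EvalueCalibration, Level, Strategy,
                               calibrate_evalues, rank_hits, search,
                               single_level_strategy)
from intronscan.synth import FixtureSpec, make_model, sample_intron
from conftest import small_spec
from oracle import brute_force_search


def _genome(seq, uid="g1"):
    return GenomeRecord(uid=uid, sequence=seq)


def _planted_genome(model, pset, rng, flank=400, at=0.7):
    """Background with one training-identical intron planted: element
    sequences of training row 0 joined by that row's spacers."""
    row = model.sequences[0][1]
    parts = []
    for it in model.layout():
        s, t = it[-1]
        parts.append(row[s:t].replace("-", ""))
    intron = to_dna("".join(parts))
    p = [at / 2, (1 - at) / 2, (1 - at) / 2, at / 2]
    bases = np.array(list("ACGT"))
    bg = lambda n: "".join(bases[rng.choice(4, size=n, p=p)])
    return bg(flank) + intron + bg(flank), flank, intron


class TestPlantedHits:
    def test_training_sequence_recovered_with_self_score(self, fixture_model):
        spec, model, pset = fixture_model
        ts = tstat(pset, model)
        strat = single_level_strategy(model, ts)
        rng = np.random.default_rng(9)
        seq, flank, intron = _planted_genome(model, pset, rng)
        hits = search(model, pset, strat, [_genome(seq)])
        assert len(hits) == 1
        h = hits[0]
        assert h.strand == "+"
        assert h.start == flank + 1 and h.end == flank + len(intron)
        # total score equals the training row's self-score
        from intronscan.profiles import self_scores
        totals = np.sum(np.vstack(list(
            self_scores(pset, model).values())), axis=0)
        assert h.score == pytest.approx(totals[0], abs=1e-9)

    def test_reverse_complement_mirrors_hit(self, fixture_model):
        spec, model, pset = fixture_model
        ts = tstat(pset, model)
        strat = single_level_strategy(model, ts)
        rng = np.random.default_rng(9)
        seq, flank, intron = _planted_genome(model, pset, rng)
        rc = revcomp_dna(seq)
        fwd_hits = search(model, pset, strat, [_genome(seq)])
        rc_hits = search(model, pset, strat, [_genome(rc)])
        assert len(fwd_hits) == len(rc_hits) == 1
        hf, hr = fwd_hits[0], rc_hits[0]
        assert hr.strand == "-"
        assert hr.score == pytest.approx(hf.score, abs=1e-9)
        L = len(seq)
        assert (hr.start, hr.end) == (L - hf.end + 1, L - hf.start + 1)

    def test_strand_symmetry_of_full_hit_sets(self, fixture_model):
        """search(revcomp(genome)) is the coordinate-mirrored hit set."""
        spec, model, pset = fixture_model
        ts = tstat(pset, model)
        strat = Strategy((Level(tuple(p for p in pset.profiles), 20.0),))
        rng = np.random.default_rng(123)
        seq = "".join(np.array(list("ACGT"))[rng.integers(0, 4, 3000)])
        L = len(seq)
        hits = search(model, pset, strat, [_genome(seq)])
        mirror = search(model, pset, strat, [_genome(revcomp_dna(seq))])
        a = sorted((h.strand, h.start, h.end, round(h.score, 6))
                   for h in hits)
        b = sorted(("+-"[h.strand == "+"], L - h.end + 1, L - h.start + 1,
                    round(h.score, 6)) for h in mirror)
        assert a == b


def _random_strategy(model, ts, rng, lossless=True):
    """Random 1-3 level partition of the model's elements with cumulative
    tstat-minima cutoffs."""
    eids = [e.element_id for e in model.elements]
    rng.shuffle(eids)
    n_levels = int(rng.integers(1, min(3, len(eids)) + 1))
    cuts = sorted(rng.choice(range(1, len(eids)), size=n_levels - 1,
                             replace=False)) if n_levels > 1 else []
    chunks = np.split(np.array(eids), cuts)
    levels = []
    cum = []
    for ch in chunks:
        cum.extend(int(x) for x in ch)
        levels.append(Level(tuple(int(x) for x in ch), ts.cutoff_for(cum)))
    return Strategy(tuple(levels))


class TestOracleEquivalence:
    @pytest.mark.parametrize("seed", range(12))
    def test_multilevel_equals_bruteforce_enumeration(self, seed):
        """On random fixtures, the staged search returns exactly the
        exhaustively enumerated hit set (spans, strands, scores)."""
        rng = np.random.default_rng(seed)
        layout = [("ss", "helix", "ss"), ("ss", "ss", "helix"),
                  ("helix", "ss", "helix")][seed % 3]
        spec = small_spec(seed, layout=layout,
                          pseudoknot=(seed % 3 == 2), conservation=0.85)
        model, pset = make_model(spec)
        ts = tstat(pset, model)
        strat = _random_strategy(model, ts, rng)
        genomes, _ = __import__("intronscan.synth", fromlist=["implant"]) \
            .implant([(model, spec)], {model.name: 2}, seed=seed + 100,
                     background_length=2500)
        hits = search(model, pset, strat, genomes)
        expected = brute_force_search(
            model, pset, strat, genomes[0].sequence, contig=genomes[0].uid)
        assert len(hits) == len(expected)
        got = sorted(hits, key=lambda h: (h.strand, h.start, h.end))
        exp = sorted(expected, key=lambda h: (h["strand"], h["start"], h["end"]))
        for h, e in zip(got, exp):
            assert (h.strand, h.start, h.end) == \
                (e["strand"], e["start"], e["end"])
            assert sorted(h.occ_spans) == sorted(e["spans"])
            assert h.score == pytest.approx(e["score"], abs=1e-9)

    def test_raising_cutoff_never_adds_hits(self, fixture_model):
        spec, model, pset = fixture_model
        ts = tstat(pset, model)
        genomes, _ = __import__("intronscan.synth", fromlist=["implant"]) \
            .implant([(model, spec)], {model.name: 3}, seed=77,
                     background_length=5000)
        eids = tuple(p for p in pset.profiles)
        base = search(model, pset, Strategy((Level(eids, 25.0),)), genomes)
        keys = lambda hs: {(h.strand, h.start, h.end) for h in hs}
        for cut in (35.0, 45.0, 60.0):
            higher = search(model, pset, Strategy((Level(eids, cut),)), genomes)
            assert keys(higher) <= keys(base)

    def test_low_cutoff_extra_level_keeps_loci(self, fixture_model):
        """Adding a level with an effectively -inf cutoff changes scores
        (more elements) but never which loci survive."""
        spec, model, pset = fixture_model
        ts = tstat(pset, model)
        genomes, _ = __import__("intronscan.synth", fromlist=["implant"]) \
            .implant([(model, spec)], {model.name: 3}, seed=78,
                     background_length=5000)
        eids = [e.element_id for e in model.elements]
        partial = Strategy((Level(tuple(eids[:-1]),
                                  ts.cutoff_for(eids[:-1])),))
        extended = Strategy((
            Level(tuple(eids[:-1]), ts.cutoff_for(eids[:-1])),
            Level((eids[-1],), -1e9),
        ))
        h1 = search(model, pset, partial, genomes)
        h2 = search(model, pset, extended, genomes)
        # compare anchor element spans (the shared part of the placement)
        anchor = lambda h: tuple(sp for sp in h.occ_spans
                                 if sp[0] != eids[-1])
        assert {(h.strand, anchor(h)) for h in h1} == \
            {(h.strand, anchor(h)) for h in h2}

    def test_unsatisfiable_bounds_yield_zero_hits(self, toy_model):
        pset = train(toy_model, on_warning=lambda m: None)
        ts = tstat(pset, toy_model)
        strat = single_level_strategy(toy_model, ts)
        # genome shorter than the minimal model span
        hits = search(toy_model, pset, strat, [_genome("ACGT")])
        assert list(hits) == []


class TestRanking:
    def test_rank_by_evalue_then_score_then_position(self):
        def mk(ev, score, start):
            from intronscan.search import Hit
            return Hit("m", "c", "+", start, start + 10, score, ev, {}, (),
                       {})
        hits = [mk(1e-3, 5.0, 50), mk(1e-8, 4.0, 10), mk(1e-3, 7.0, 99),
                mk(1e-3, 7.0, 20)]
        ranked = rank_hits(hits)
        assert [h.start for h in ranked] == [10, 20, 99, 50]


class TestEvalues:
    def test_evalue_decreasing_and_length_linear(self):
        calib = EvalueCalibration(mu=5.0, beta=2.0, calib_len=1000,
                                  n_shuffles=50)
        e1 = calib.evalue(10.0, 10_000)
        e2 = calib.evalue(11.0, 10_000)
        assert e2 < e1
        assert calib.evalue(10.0, 20_000) == pytest.approx(2 * e1)
        # at s = mu the E-value equals the database-length scaling factor
        assert calib.evalue(5.0, 5000) == pytest.approx(5.0)
        big = calib.evalue(1e6, 10_000)
        assert big == pytest.approx(0.0, abs=1e-12)

    def test_score_at_inverts_evalue(self):
        calib = EvalueCalibration(mu=-3.0, beta=1.7, calib_len=2000,
                                  n_shuffles=50)
        s = calib.score_at(0.01, 500_000)
        assert calib.evalue(s, 500_000) == pytest.approx(0.01)

    def test_calibration_reproducible_and_sane(self, fixture_model):
        spec, model, pset = fixture_model
        ts = tstat(pset, model)
        strat = single_level_strategy(model, ts)
        c1 = calibrate_evalues(model, pset, strat, n_shuffles=40,
                               shuffle_len=1000, seed=3)
        c2 = calibrate_evalues(model, pset, strat, n_shuffles=40,
                               shuffle_len=1000, seed=3)
        assert (c1.mu, c1.beta) == (c2.mu, c2.beta)
        assert c1.beta > 0
        # random-sequence maxima sit far below the training scores
        assert c1.mu < ts.total.min
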