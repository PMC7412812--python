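"""Pool designer: de Bruijn backbone, tiling, excision, split, prefix, audits."""

import numpy as np
import pytest

from rbpkit._kmers import DNA_ALPHABET
from rbpkit.io import write_pool_fasta
from rbpkit.pool import (
    PoolDesignError,
    PoolDesignSpec,
    ProbePool,
    assign_sets,
    design_pool,
    excise_forbidden,
    expand_forbidden_kmers,
    forbidden_junction_prefixes,
    generate_de_bruijn,
    screen_hairpins,
    tile_probes,
    tiling_starts,
    verify_coverage,
)
from conftest import naive_kmer_counts

FORBIDDEN = ("GCTCTTC", "CGAGAAG")


class TestDeBruijn:
    @pytest.mark.parametrize("order", [1, 2, 3, 4, 5, 6])
    def test_every_word_occurs_exactly_once_cyclically(self, order):
        s = generate_de_bruijn(order)
        assert len(s) == 4**order + order - 1
        counts = naive_kmer_counts([s], order)
        assert len(counts) == 4**order
        assert set(counts.values()) == {1}

    def test_order_one_is_the_alphabet(self):
        assert generate_de_bruijn(1) == "ACGT"

    def test_order_two_dinucleotides(self):
        s = generate_de_bruijn(2)
        assert len(s) == 17
        assert sorted(naive_kmer_counts([s], 2)) == sorted(
            a + b for a in DNA_ALPHABET for b in DNA_ALPHABET
        )

    def test_deterministic_and_lexicographically_least(self):
        assert generate_de_bruijn(3) == generate_de_bruijn(3)
        assert generate_de_bruijn(2).startswith("AA")  # least rotation starts with A^order

    @pytest.mark.parametrize("bad", [0, -3])
    def test_nonpositive_order_rejected(self, bad):
        with pytest.raises(ValueError):
            generate_de_bruijn(bad)

    def test_duplicate_alphabet_rejected(self):
        with pytest.raises(ValueError):
            generate_de_bruijn(2, "ACCA")


class TestTiling:
    def test_toy_schedule_is_evenly_spread(self):
        spec = PoolDesignSpec(
            order=2, probe_count=3, variable_length=5, pool_audit_k=2, set_audit_k=2
        )
        starts = tiling_starts(12, spec)
        assert starts.tolist() == [0, 3, 7]
        assert starts[-1] + spec.variable_length == 12

    def test_default_schedule_step_counts(self):
        # 241,399 windows of 35 nt over the 4^11 + 10 nt linearized backbone:
        # the exact-count schedule takes 150,885 steps of 17 and 90,513 of 18
        spec = PoolDesignSpec()
        starts = tiling_starts(4**11 + 10, spec)
        steps = np.diff(starts)
        assert len(starts) == 241_399
        assert starts[0] == 0 and starts[-1] == 4**11 + 10 - 35
        vals, counts = np.unique(steps, return_counts=True)
        assert dict(zip(vals.tolist(), counts.tolist())) == {17: 150_885, 18: 90_513}

    def test_single_probe_is_the_prefix(self):
        spec = PoolDesignSpec(
            order=2, probe_count=1, variable_length=5, pool_audit_k=3, set_audit_k=2
        )
        p = tile_probes("ACGTACGTACGT", spec)
        assert len(p) == 1 and p.variable_seq(0) == "ACGTA"

    def test_infeasible_combination_rejected(self):
        spec = PoolDesignSpec(
            order=2, probe_count=2, variable_length=5, pool_audit_k=3, set_audit_k=2
        )
        with pytest.raises(PoolDesignError):
            tiling_starts(100, spec)  # step 95 leaves no overlap

    def test_every_audit_kmer_occurrence_is_contained(self, toy_spec):
        backbone = generate_de_bruijn(toy_spec.order)
        starts = tiling_starts(len(backbone), toy_spec)
        k, w = toy_spec.pool_audit_k, toy_spec.variable_length
        # every k-mer start position of the backbone must lie wholly inside
        # at least one window
        covered = np.zeros(len(backbone) - k + 1, dtype=bool)
        for s in starts:
            covered[s : s + w - k + 1] = True
        assert covered.all()


class TestExcision:
    def test_repaired_probe_is_clean_and_logged(self):
        seq = "AAGCTCTTCAAGGTC"
        pool = ProbePool.from_sequences([seq])
        spec = PoolDesignSpec(
            order=5, probe_count=1, variable_length=15, pool_audit_k=5, set_audit_k=3
        )
        out, log = excise_forbidden(pool, spec)
        repaired = out.variable_seq(0)
        assert all(f not in repaired for f in FORBIDDEN)
        assert len(log) == 1
        pid, posn, old, new = log[0]
        assert posn == 5 and old == "C" and new != old  # center of the occurrence

    def test_clean_probe_untouched(self):
        pool = ProbePool.from_sequences(["ACGTACGTACGTACG"])
        spec = PoolDesignSpec(
            order=5, probe_count=1, variable_length=15, pool_audit_k=5, set_audit_k=3
        )
        out, log = excise_forbidden(pool, spec)
        assert out.variable_seq(0) == "ACGTACGTACGTACG" and log == []

    def test_no_forbidden_site_survives_in_designed_pool(self, toy_design):
        for i in range(len(toy_design.pool)):
            s = toy_design.pool.variable_seq(i)
            assert all(f not in s for f in FORBIDDEN)


class TestSetsAndPrefix:
    def test_alternating_labels(self):
        pool = assign_sets(ProbePool.from_sequences(["AAAA", "CCCC", "GGGG", "TTTT"]))
        assert [r.set_label for r in pool] == ["A", "B", "A", "B"]

    def test_single_probe_gets_set_a(self):
        pool = assign_sets(ProbePool.from_sequences(["AAAA"]))
        assert pool.record(0).set_label == "A"

    def test_split_of_default_probe_count_is_balanced(self):
        n = 241_399
        labels = np.where(np.arange(n) % 2 == 0, "A", "B")
        assert (labels == "A").sum() == 120_700 and (labels == "B").sum() == 120_699

    def test_junction_prefix_enumeration(self):
        # AGA can never complete a forbidden 7-mer across the junction; AGG
        # does exactly when the variable region starts with CTCTTC
        assert forbidden_junction_prefixes("AGA", FORBIDDEN) == set()
        assert forbidden_junction_prefixes("AGG", FORBIDDEN) == {"CTCTTC"}

    def test_rna_seq_is_prefixed_and_transcribed(self, toy_design):
        rec = toy_design.pool.record(0)
        assert rec.rna_seq.startswith("AGA")
        assert len(rec.rna_seq) == 3 + len(rec.variable_seq) <= 41
        assert set(rec.rna_seq) <= set("ACGU")
        assert rec.rna_seq[3:] == rec.variable_seq.replace("T", "U")


class TestCoverageAudit:
    def test_hand_counted_example(self):
        pool = assign_sets(ProbePool.from_sequences(["ACGT", "ACGT"]))
        rep = verify_coverage(pool, k=2, scope="pool", threshold=2)
        assert rep.min_count == 0 and not rep.passed
        assert "AA" in rep.argmin_kmers
        assert rep.total_kmers_counted == 6

    def test_excluded_kmers_do_not_set_the_minimum(self):
        pool = assign_sets(ProbePool.from_sequences(["ACGT", "ACGT"]))
        excl = [a + b for a in DNA_ALPHABET for b in DNA_ALPHABET if a + b not in ("AC", "CG", "GT")]
        rep = verify_coverage(pool, k=2, scope="pool", threshold=2, excluded=excl)
        assert rep.min_count == 2 and rep.passed

    def test_k_larger_than_variable_length_rejected(self):
        pool = ProbePool.from_sequences(["ACGT"])
        with pytest.raises(ValueError):
            verify_coverage(pool, k=5)

    @pytest.mark.parametrize("k,scope", [(3, "pool"), (5, "pool"), (3, "setA"), (3, "setB")])
    def test_agrees_with_naive_oracle(self, toy_design, k, scope):
        pool = toy_design.pool
        mask = pool.scope_mask(scope)
        seqs = [pool.variable_seq(i) for i in np.nonzero(mask)[0]]
        oracle = naive_kmer_counts(seqs, k)
        full_min = min(
            oracle.get("".join(km), 0)
            for km in __import__("itertools").product(DNA_ALPHABET, repeat=k)
        )
        rep = verify_coverage(pool, k=k, scope=scope, threshold=1)
        assert rep.min_count == full_min

    def test_expand_forbidden_9mers(self):
        ex9 = expand_forbidden_kmers(FORBIDDEN, 9)
        assert len(ex9) == 96  # 2 sites x 3 offsets x 16 flanks, no overlap
        assert all(any(f in e for f in FORBIDDEN) for e in ex9)
        assert expand_forbidden_kmers(FORBIDDEN, 7) == sorted(FORBIDDEN)
        assert expand_forbidden_kmers(FORBIDDEN, 5) == []


class TestDesignPool:
    def test_toy_design_passes_all_audits(self, toy_spec, toy_design):
        assert len(toy_design.pool) == toy_spec.probe_count
        assert toy_design.passed
        for rep in toy_design.reports:
            assert rep.min_count >= rep.threshold

    def test_byte_identical_fasta_across_runs(self, toy_spec, tmp_path):
        paths = []
        for run in (1, 2):
            res = design_pool(toy_spec)
            p = tmp_path / f"pool{run}.fa"
            write_pool_fasta(res.pool, p)
            paths.append(p.read_bytes())
        assert paths[0] == paths[1]

    def test_infeasible_floor_reports_honestly(self):
        spec = PoolDesignSpec(
            order=5, probe_count=1, variable_length=15, pool_audit_k=5, set_audit_k=3
        )
        res = design_pool(spec)
        assert not res.passed
        assert res.reports[0].min_count == 0  # one 15-nt probe holds 11 5-mers

    def test_spec_invariants_enforced(self):
        with pytest.raises(ValueError):
            PoolDesignSpec(variable_length=40, max_rna_length=41)
        with pytest.raises(ValueError):
            PoolDesignSpec(forbidden_kmers=("ACGT",))
        with pytest.raises(ValueError):
            PoolDesignSpec(probe_count=0)


class TestHairpinScreen:
    def test_perfect_stem_is_flagged_and_random_probe_is_not(self):
        stem = "ACCGGTTA"
        rc = "TAACCGGT"
        hairpin = stem + "AAAA" + rc + "A" * (35 - 20)
        benign = "ACGTAGCTAGGATCCATGCATGACTGATCGATAGC"
        pool = ProbePool.from_sequences([hairpin, benign])
        assert screen_hairpins(pool, min_stem=8) == ["probe_000000"]
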