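"""Tag collapsing and Hamming assignment, checked against brute force."""

from __future__ import annotations

import numpy as np
import pytest

import mirprof as m
from mirprof.quantify import count_assigned

from conftest import make_read


def brute_force_assign(tag: str, reference: m.MatureReference,
                       max_mismatch: int) -> tuple[str, int] | None:
    """All-pairs Hamming oracle: equal length only, smallest-id tie break."""
    best = None
    for name, seq in reference.items():
        if len(seq) != len(tag):
            continue
        d = sum(1 for a, b in zip(tag, seq) if a != b)
        if d <= max_mismatch and (best is None or (d, name) < best):
            best = (d, name)
    return (best[1], best[0]) if best else None


def random_tags(reference: m.MatureReference, n: int, seed: int) -> list[str]:
    """Mix of exact, mutated and unrelated sequences."""
    rng = np.random.default_rng(seed)
    seqs = [seq for _, seq in reference.items()]
    tags = set()
    for _ in range(n):
        kind = rng.integers(0, 3)
        if kind == 0:
            tags.add(seqs[rng.integers(len(seqs))])
        elif kind == 1:
            s = list(seqs[rng.integers(len(seqs))])
            for pos in rng.choice(len(s), size=min(rng.integers(1, 5), len(s)),
                                  replace=False):
                s[pos] = "ACGT"[rng.integers(4)]
            tags.add("".join(s))
        else:
            length = int(rng.integers(18, 27))
            tags.add("".join("ACGT"[i] for i in rng.integers(0, 4, length)))
    return sorted(tags)


class TestCollapse:
    def test_multiset_partition(self):
        reads = [make_read(f"r{i}", "ACGT" * 5) for i in range(3)]
        reads += [make_read(f"s{i}", "TTGA" * 5) for i in range(2)]
        tagset = m.collapse_tags(reads, library="lib1")
        assert tagset.tags == {"ACGT" * 5: 3, "TTGA" * 5: 2}

    def test_empty_input(self):
        assert m.collapse_tags([]).tags == {}

    def test_total_conserved_on_random_stream(self):
        rng = np.random.default_rng(0)
        reads = [
            make_read(f"r{i}", "".join("ACGT"[j] for j in rng.integers(0, 4, 20)))
            for i in range(1000)
        ]
        assert m.collapse_tags(reads).total_reads == 1000


class TestMatchTags:
    def test_exact_match_zero_mismatches(self, small_reference):
        name = small_reference.names[7]
        table = m.match_tags([small_reference[name]], small_reference)
        assert table.assignments[small_reference[name]] == (name, 0)

    def test_two_mismatches_assigned_three_unassigned(self):
        ref = m.MatureReference({"m1": "ACGTACGTACGTACGTACGT"})
        base = ref["m1"]
        two = "TT" + base[2:]
        three = "TTT" + base[3:]
        table = m.match_tags([two, three], ref)
        assert table.assignments[two] == ("m1", 2)
        assert three in table.unassigned

    def test_length_must_match(self):
        ref = m.MatureReference({"m1": "ACGTACGTACGTACGTACGTAC"})  # 22 nt
        prefix21 = ref["m1"][:21]
        table = m.match_tags([prefix21], ref)
        assert prefix21 in table.unassigned

    def test_tie_breaks_to_smallest_id(self):
        # two references both at distance 1 from the tag
        ref = m.MatureReference({
            "m-b": "AAAAAAAAAAAAAAAAAAAC",
            "m-a": "AAAAAAAAAAAAAAAAAAAG",
        })
        tag = "AAAAAAAAAAAAAAAAAAAT"
        table = m.match_tags([tag], ref)
        assert table.assignments[tag] == ("m-a", 1)

    @pytest.mark.parametrize("seed,n_tags,n_refs", [(0, 200, 30), (1, 500, 50)])
    def test_oracle_equivalence(self, seed, n_tags, n_refs):
        ref = m.generate_reference(n_refs, seed=seed + 100)
        tags = random_tags(ref, n_tags, seed)
        table = m.match_tags(tags, ref)
        for tag in tags:
            expected = brute_force_assign(tag, ref, 2)
            if expected is None:
                assert tag in table.unassigned
            else:
                assert table.assignments[tag] == expected

    def test_mismatch_zero_assignments_nest_in_mismatch_two(self, small_reference):
        tags = random_tags(small_reference, 300, seed=5)
        strict = m.match_tags(tags, small_reference, max_mismatch=0)
        loose = m.match_tags(tags, small_reference, max_mismatch=2)
        assert strict.assigned_tags <= loose.assigned_tags

    def test_non_dna_reference_rejected(self):
        with pytest.raises(ValueError, match="non-ACGT"):
            m.MatureReference({"m1": "ACGTXCGTACGTACGTACGT"})


class TestCountMatrix:
    def test_counts_sum_per_mirna(self):
        ref = m.MatureReference({"m1": "A" * 19 + "C", "m2": "C" * 19 + "A"})
        tagset = m.TagSet(library="CK", tags={"A" * 19 + "C": 3,
                                              "A" * 18 + "GC": 2,
                                              "C" * 19 + "A": 5})
        table = m.match_tags(tagset, ref)
        counts = count_assigned(tagset, table, ref)
        assert counts["m1"] == 5 and counts["m2"] == 5

    def test_conservation_assigned_plus_unassigned(self, small_reference):
        tags = random_tags(small_reference, 400, seed=2)
        rng = np.random.default_rng(3)
        tagset = m.TagSet(
            library="CK",
            tags={t: int(rng.integers(1, 10)) for t in tags},
        )
        table = m.match_tags(tagset, small_reference)
        counts = count_assigned(tagset, table, small_reference)
        unassigned_reads = sum(tagset.tags[t] for t in table.unassigned)
        assert counts.sum() + unassigned_reads == tagset.total_reads

    def test_zero_assignment_matrix_keeps_reference_and_sizes(self, small_reference):
        tagset = m.TagSet(library="CK", tags={})
        table = m.match_tags(tagset, small_reference)
        matrix = m.build_count_matrix([tagset], [table], {"CK": 123},
                                      small_reference)
        assert (matrix.counts["CK"] == 0).all()
        assert list(matrix.counts.index) == small_reference.names
        assert matrix.lib_sizes["CK"] == 123

    def test_count_matrix_tsv_and_triplet_roundtrip(self, tmp_path, small_reference):
        from mirprof.io import (read_count_matrix, write_count_matrix,
                                write_count_triplets)
        tags = random_tags(small_reference, 100, seed=6)
        tagset = m.TagSet(library="CK", tags={t: 2 for t in tags})
        table = m.match_tags(tagset, small_reference)
        matrix = m.build_count_matrix([tagset], [table],
                                      {"CK": tagset.total_reads},
                                      small_reference)
        back = read_count_matrix(write_count_matrix(matrix, tmp_path / "c.tsv"))
        assert back.counts.equals(matrix.counts)
        assert back.lib_sizes.equals(matrix.lib_sizes)
        triplets = write_count_triplets(matrix, tmp_path / "c.triplets.tsv")
        body = [l for l in triplets.read_text().splitlines()
                if not l.startswith("#") and not l.startswith("mirna_id")]
        assert sum(int(l.split("\t")[2]) for l in body) == \
            int(matrix.counts["CK"].sum())

    def test_library_collision_fails(self, small_reference):
        tagset = m.TagSet(library="CK", tags={})
        table = m.match_tags(tagset, small_reference)
        with pytest.raises(ValueError, match="collision"):
            m.build_count_matrix([tagset, tagset], [table, table],
                                 {"CK": 10}, small_reference)

    def test_noise_free_simulation_quantifies_exactly(self, tmp_path):
        """With no errors and no junk, the pipeline recovers the realised
        source tallies read for read."""
        from mirprof.simulate import CONTAMINANT_CLASSES
        ref = m.generate_reference(40, seed=21)
        cfg = m.SimConfig(
            n_mirnas=40, reads_per_library=5000, n_treatment=2, seed=21,
            error_rate=0.0,
            contaminant_fractions={c: 0.0 for c in CONTAMINANT_CLASSES},
        )
        out = m.generate_experiment(ref, cfg, tmp_path)
        quant = m.quantify_libraries(out.fastq_paths, ref)
        assert quant.count_matrix.counts.equals(out.truth.realized_counts)
        assert (quant.count_matrix.lib_sizes == cfg.reads_per_library).all()
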