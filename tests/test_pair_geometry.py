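"""Strand extraction, pair enumeration, orientation and registration."""

import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from strandpairs.dssp_io import ChainRecord, ResidueRecord
from strandpairs.pair_geometry import (
    ANTIPARALLEL,
    PARALLEL,
    BetaStrand,
    StrandPair,
    build_sheets,
    classify_orientation,
    compute_registration,
    enumerate_pairs,
    extract_strands,
    pairs_from_chains,
)
from strandpairs.synthetic_data import (
    SyntheticDataset,
    make_pair_config,
    recover_pairs,
)

from conftest import brute_force_overlap, chain_from_ss


def segmentation_oracle(ss, breaks=()):
    """Brute-force maximal-'E'-run lengths, split at break positions."""
    lengths, run = [], 0
    for pos, s in enumerate(ss):
        if pos in breaks and run:
            lengths.append(run)
            run = 0
        if s == "E":
            run += 1
        elif run:
            lengths.append(run)
            run = 0
    if run:
        lengths.append(run)
    return lengths


class TestExtractStrands:
    @pytest.mark.parametrize(
        "ss,breaks,expected",
        [
            ("CCEEEECCEEC", (), [4, 2]),
            ("CBCBC", (), []),  # isolated bridges are not strands
            ("EEEEE", (2,), [2, 3]),
            ("E", (), [1]),  # single-residue strands count
            ("", (), []),
        ],
    )
    def test_examples(self, ss, breaks, expected):
        strands = extract_strands(chain_from_ss(ss, breaks))
        assert [s.length for s in strands] == expected
        assert [s.strand_ordinal for s in strands] == list(
            range(1, len(expected) + 1)
        )

    @settings(derandomize=True, max_examples=100, deadline=None)
    @given(
        ss=st.text(alphabet="EHC B", min_size=0, max_size=40),
        breaks=st.sets(st.integers(1, 39), max_size=3),
    )
    def test_matches_brute_force_segmentation(self, ss, breaks):
        breaks = {b for b in breaks if b < len(ss)}
        strands = extract_strands(chain_from_ss(ss, tuple(sorted(breaks))))
        assert [s.length for s in strands] == segmentation_oracle(ss, breaks)


def wire_ladder(chain, strand_ranges, links):
    """Set bp1 links between residues (by dssp_index) on a chain in place."""
    by_index = {r.dssp_index: i for i, r in enumerate(chain.residues)}
    for a, b in links:
        for x, y in ((a, b), (b, a)):
            i = by_index[x]
            r = chain.residues[i]
            if r.bp1 == 0:
                chain.residues[i] = ResidueRecord(
                    **{**vars(r), "bp1": y, "bridge_label1": "A"}
                )
            else:
                chain.residues[i] = ResidueRecord(
                    **{**vars(r), "bp2": y, "bridge_label2": "A"}
                )
    return chain


class TestEnumeratePairs:
    def test_unlinked_strands_make_no_pair(self):
        chain = chain_from_ss("EEECCEEE")
        assert pairs_from_chains([chain]) == []

    def test_ladder_of_k_strands_yields_k_minus_1_pairs(self):
        # 4 strands of length 3 in one ladder: 1-2, 2-3, 3-4
        ss = "EEEC" * 4
        chain = chain_from_ss(ss)
        starts = [1, 5, 9, 13]
        links = []
        for s, t in zip(starts, starts[1:]):
            links += [(s + j, t + 2 - j) for j in range(3)]
        wire_ladder(chain, None, links)
        pairs = pairs_from_chains([chain])
        assert len(pairs) == 3
        assert all(p.PL == 3 and p.orientation == ANTIPARALLEL for p in pairs)

    def test_three_sheet_topology_counts(self):
        """Ten strands wired into sheets of 3, 4 and 3 strands give
        2 + 3 + 2 = 7 adjacent pairs — the partnership-graph bookkeeping
        for a small alpha/beta protein."""
        ss = ("EEEC" * 10)
        chain = chain_from_ss(ss)
        starts = [1 + 4 * i for i in range(10)]
        sheets = [starts[0:3], starts[3:7], starts[7:10]]
        links = []
        for members in sheets:
            for s, t in zip(members, members[1:]):
                links += [(s + j, t + 2 - j) for j in range(3)]
        wire_ladder(chain, None, links)
        pairs = pairs_from_chains([chain])
        assert len(pairs) == 7
        graphs = build_sheets(extract_strands(chain), pairs)
        assert [len(g.strands) for g in graphs] == [3, 4, 3]
        assert [len(g.pairs) for g in graphs] == [2, 3, 2]
        assert all(not g.bifurcated for g in graphs)

    def test_bridge_to_non_strand_residue_ignored(self, caplog):
        chain = chain_from_ss("EEECC")
        # residue 2 claims residue 5 (a coil) as partner
        chain.residues[1] = ResidueRecord(**{**vars(chain.residues[1]), "bp1": 5})
        import logging

        with caplog.at_level(logging.WARNING, logger="strandpairs.pair_geometry"):
            pairs = pairs_from_chains([chain])
        assert pairs == []
        assert any("link ignored" in r.message for r in caplog.records)

    def test_interchain_pair_tagged(self):
        a = chain_from_ss("EEE", chain_id="A")
        b = chain_from_ss("EEE", chain_id="B", start_index=10)
        links = [(1, 12), (2, 11), (3, 10)]
        wire_ladder(a, None, [])
        by_index = {r.dssp_index: r for r in a.residues + b.residues}
        for x, y in links:
            for u, v in ((x, y), (y, x)):
                r = by_index[u]
                src = a if r.chain_id == "A" else b
                i = src.residues.index(r)
                src.residues[i] = ResidueRecord(**{**vars(r), "bp1": v})
                by_index[u] = src.residues[i]
        (pair,) = pairs_from_chains([a, b])
        assert pair.interchain
        assert pair.strand1.chain_id == "A"
        assert pair.orientation == ANTIPARALLEL


def pair_with_map(map_, sl1=None, sl2=None):
    n1 = sl1 or max(a for a, _ in map_) - min(a for a, _ in map_) + 1
    lo1 = min(a for a, _ in map_)
    lo2 = min(b for _, b in map_)
    n2 = sl2 or max(b for _, b in map_) - lo2 + 1
    s1 = BetaStrand("A", list(range(lo1, lo1 + n1)), strand_ordinal=1)
    s2 = BetaStrand("A", list(range(lo2, lo2 + n2)), strand_ordinal=2)
    return StrandPair(strand1=s1, strand2=s2, bridged_map=list(map_))


class TestOrientation:
    def test_increasing_partners_are_parallel(self):
        p = pair_with_map([(10, 20), (11, 21), (12, 22)])
        assert classify_orientation(p) == PARALLEL

    def test_decreasing_partners_are_antiparallel(self):
        p = pair_with_map([(10, 22), (11, 21), (12, 20)])
        assert classify_orientation(p) == ANTIPARALLEL

    def test_non_monotonic_takes_majority_and_flags_bulge(self):
        p = pair_with_map([(10, 20), (11, 22), (12, 21), (13, 23)])
        assert classify_orientation(p) == PARALLEL
        assert p.bulged

    def test_single_bridge_without_label_defaults_antiparallel(self, caplog):
        import logging

        p = pair_with_map([(10, 20)])
        with caplog.at_level(logging.WARNING, logger="strandpairs.pair_geometry"):
            assert classify_orientation(p) == ANTIPARALLEL
        assert any("indeterminate" in r.message for r in caplog.records)

    def test_single_bridge_parallel_recovered_from_ladder_label(self):
        """A one-rung parallel ladder is only recoverable through the
        lowercase ladder letter DSSP wrote for it."""
        cfg = make_pair_config(1, 1, 0, PARALLEL)
        (pair,) = recover_pairs(SyntheticDataset(configs=[cfg], seed=0))
        assert pair.orientation == PARALLEL


class TestRegistration:
    @pytest.mark.parametrize(
        "sl1,sl2,offset,expected",
        [
            (4, 4, 0, (4, 0, 0, 4)),  # terminal-aligned equal lengths
            (6, 4, 0, (4, 2, 0, 6)),  # containment, one-sided extension
            (5, 5, 2, (3, 2, 2, 7)),  # shifted register, both extensions
        ],
    )
    def test_examples_via_pipeline(self, sl1, sl2, offset, expected):
        cfg = make_pair_config(sl1, sl2, offset, ANTIPARALLEL)
        (pair,) = recover_pairs(SyntheticDataset(configs=[cfg], seed=0))
        assert (pair.PL, pair.Et1, pair.Et2, pair.EL) == expected
        assert not pair.bulged

    def test_small_sweep_matches_interval_overlap_oracle(self):
        for sl1 in range(1, 9):
            for sl2 in range(1, 9):
                for o in range(-(sl2 - 1), sl1):
                    cfg = make_pair_config(sl1, sl2, o, ANTIPARALLEL)
                    want = brute_force_overlap(sl1, sl2, o)
                    assert cfg.truth_PL == want

    def test_duplicate_link_collapsed(self):
        """PL counts distinct residues, not bonds."""
        p = pair_with_map([(10, 20), (10, 20), (11, 21)])
        compute_registration(p)
        assert p.PL == 2 and not p.bulged

    def test_bulged_when_noncontiguous(self):
        p = pair_with_map([(10, 20), (12, 22)], sl1=3, sl2=3)
        compute_registration(p)
        assert p.bulged

    def test_empty_map_rejected(self):
        p = pair_with_map([(10, 20)])
        p.bridged_map = []
        with pytest.raises(ValueError):
            compute_registration(p)

    def test_registration_identities_on_random_pairs(self, small_dataset_pairs):
        for p in small_dataset_pairs:
            if p.bulged:
                continue
            assert p.EL == p.PL + p.Et1 + p.Et2
            assert p.Et1 - p.Et2 == p.SL1 - p.SL2
            assert 1 <= p.PL <= min(p.SL1, p.SL2)
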