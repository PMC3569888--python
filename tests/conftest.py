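import numpy as np
import pytest

from strandpairs.dssp_io import ChainRecord, ResidueRecord
from strandpairs.pair_geometry import BetaStrand, StrandPair


def chain_from_ss(ss: str, breaks=(), chain_id="A", start_index=1):
    """Build a ChainRecord from a secondary-structure string.

    ``breaks`` are residue-list positions where a chain break occurs; the
    DSSP index skips one there, as a break line would in a real file.
    """
    residues = []
    idx = start_index - 1
    ss = ss.replace("C", " ")  # DSSP writes coil as a blank column
    for pos, state in enumerate(ss):
        idx += 1
        if pos in breaks:
            idx += 1  # the break line consumes an index
        residues.append(
            ResidueRecord(
                dssp_index=idx,
                chain_id=chain_id,
                pdb_resnum=idx,
                amino_acid="A",
                ss_state=state,
            )
        )
    return ChainRecord(chain_id=chain_id, residues=residues, break_positions=list(breaks))


def make_pair(sl1, sl2, pl, orientation="antiparallel", bulged=False):
    """A StrandPair with its registration fields set directly — enough for
    every ratio/summary operation, which read only the decomposition."""
    s1 = BetaStrand(chain_id="A", residues=list(range(1, sl1 + 1)), strand_ordinal=1)
    s2 = BetaStrand(
        chain_id="A", residues=list(range(100, 100 + sl2)), strand_ordinal=2
    )
    return StrandPair(
        strand1=s1,
        strand2=s2,
        orientation=orientation,
        SL1=sl1,
        SL2=sl2,
        PL=pl,
        Et1=sl1 - pl,
        Et2=sl2 - pl,
        EL=sl1 + sl2 - pl,
        bulged=bulged,
    )


def brute_force_overlap(sl1: int, sl2: int, offset: int) -> int:
    """Independent oracle: count frame positions covered by both strands."""
    return len(set(range(sl1)) & set(range(offset, offset + sl2)))


@pytest.fixture(scope="session")
def small_dataset():
    """A moderate seeded synthetic dataset shared by read-only tests."""
    from strandpairs.synthetic_data import sample_dataset

    return sample_dataset(2000, seed=12345)


@pytest.fixture(scope="session")
def small_dataset_pairs(small_dataset):
    from strandpairs.synthetic_data import recover_pairs

    return recover_pairs(small_dataset)
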