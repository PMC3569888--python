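"""Reading, filtering and writing classic fixed-column DSSP files.

Only the columns this analysis needs are interpreted: the sequential DSSP
index, PDB numbering, chain id, amino acid, summary secondary-structure
state, the two bridge-partner indices (BP1/BP2) with their ladder labels,
and the sheet label.  The mmCIF-flavoured DSSP output is not supported.

Chain breaks appear in DSSP as lines with ``!`` in the amino-acid column;
they are recorded as break positions, never as residues.  A file that lists
the same chain id again after a break is treated as one chain with a break,
which matches how DSSP writes discontinuous chains.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field, replace
from typing import Iterable

logger = logging.getLogger(__name__)

#: Sentinel marking the start of the fixed-column residue table.
RESIDUE_TABLE_SENTINEL = "#  RESIDUE AA STRUCTURE BP1 BP2"

#: Summary secondary-structure states emitted by DSSP.
SS_ALPHABET = frozenset("HBEGITS ")


class DSSPFormatError(ValueError):
    """The stream is not recognisable as a DSSP file."""


class DSSPParseError(ValueError):
    """A residue-table line violates the fixed-column layout or an invariant."""

    def __init__(self, message: str, line_number: int | None = None):
        self.line_number = line_number
        if line_number is not None:
            message = f"line {line_number}: {message}"
        super().__init__(message)


@dataclass(frozen=True)
class ResidueRecord:
    """One line of the DSSP residue table.

    ``bp1``/``bp2`` are the DSSP indices of the bridge partners (0 = none).
    ``bridge_label1``/``bridge_label2`` carry the ladder letters printed next
    to the partners: lowercase marks a parallel bridge, uppercase an
    antiparallel one.  Disulfide-bonded cysteines, which DSSP writes as
    lowercase letters, are normalised to ``C`` with ``disulfide`` set.
    """

    dssp_index: int
    chain_id: str
    pdb_resnum: int
    insertion_code: str = " "
    amino_acid: str = "A"
    ss_state: str = " "
    bp1: int = 0
    bp2: int = 0
    sheet_label: str = " "
    bridge_label1: str = " "
    bridge_label2: str = " "
    disulfide: bool = False


@dataclass
class ChainRecord:
    """All residues of one chain, in file order, break lines excluded.

    ``break_positions`` holds indices ``i`` such that a chain break occurs
    between ``residues[i-1]`` and ``residues[i]``.
    """

    chain_id: str
    residues: list[ResidueRecord] = field(default_factory=list)
    break_positions: list[int] = field(default_factory=list)

    def __len__(self) -> int:
        return len(self.residues)

    def ss_string(self) -> str:
        return "".join(r.ss_state for r in self.residues)


@dataclass(frozen=True)
class FilterPolicy:
    """Chain-level retention policy.

    require_beta
        Drop chains with no extended ('E') residue; a chain without a
        beta-sheet contributes nothing to pairing statistics.
    reject_nonstandard
        Drop chains containing an unknown-residue marker ('X'), which DSSP
        emits for nonstandard residue names (modified or ligand-bound
        residues).
    """

    require_beta: bool = True
    reject_nonstandard: bool = True


REASON_NO_BETA = "no-beta-sheet"
REASON_NONSTANDARD = "nonstandard-residue"


def _parse_residue_line(line: str, lineno: int) -> ResidueRecord:
    if len(line) < 34:
        raise DSSPParseError("residue line shorter than fixed-column layout", lineno)
    try:
        dssp_index = int(line[0:5])
        pdb_resnum = int(line[5:10])
        bp1 = int(line[25:29])
        bp2 = int(line[29:33])
    except ValueError as exc:
        raise DSSPParseError(f"malformed fixed column: {exc}", lineno) from None
    aa = line[13]
    disulfide = False
    if aa.islower():
        # DSSP labels SS-bonded cysteines with lowercase letters.
        aa = "C"
        disulfide = True
    ss = line[16]
    if ss not in SS_ALPHABET:
        raise DSSPParseError(f"unknown secondary-structure state {ss!r}", lineno)
    return ResidueRecord(
        dssp_index=dssp_index,
        chain_id=line[11],
        pdb_resnum=pdb_resnum,
        insertion_code=line[10],
        amino_acid=aa,
        ss_state=ss,
        bp1=bp1,
        bp2=bp2,
        sheet_label=line[33] if len(line) > 33 else " ",
        bridge_label1=line[23],
        bridge_label2=line[24],
        disulfide=disulfide,
    )


def parse_dssp(text: str | Iterable[str]) -> list[ChainRecord]:
    """Parse DSSP-format text into one :class:`ChainRecord` per chain.

    Parameters
    ----------
    text
        The DSSP file content, as a string or an iterable of lines.  A
        header block must precede the residue table, whose first line
        contains ``#  RESIDUE AA STRUCTURE BP1 BP2``.

    Raises
    ------
    DSSPFormatError
        If the residue-table sentinel is missing.
    DSSPParseError
        On malformed fixed columns, non-increasing DSSP indices, or bridge
        partners referencing a DSSP index absent from the file.
    """
    lines = text.splitlines() if isinstance(text, str) else [l.rstrip("\n") for l in text]
    table_start = None
    for i, line in enumerate(lines):
        if RESIDUE_TABLE_SENTINEL in line:
            table_start = i + 1
            break
    if table_start is None:
        raise DSSPFormatError(
            f"not a DSSP file: residue-table header {RESIDUE_TABLE_SENTINEL!r} not found"
        )

    chains: dict[str, ChainRecord] = {}
    order: list[str] = []
    seen_indices: set[int] = set()
    last_index = 0
    last_chain: str | None = None
    pending_break = False

    for lineno0, line in enumerate(lines[table_start:], start=table_start + 1):
        if not line.strip():
            continue
        if len(line) > 13 and line[13] == "!":
            # Chain-break line: consumes a DSSP index, carries no residue.
            try:
                idx = int(line[0:5])
            except ValueError:
                raise DSSPParseError("malformed index on break line", lineno0) from None
            if idx <= last_index:
                raise DSSPParseError("DSSP index not strictly increasing", lineno0)
            last_index = idx
            pending_break = True
            continue
        rec = _parse_residue_line(line, lineno0)
        if rec.dssp_index <= last_index:
            raise DSSPParseError("DSSP index not strictly increasing", lineno0)
        last_index = rec.dssp_index
        seen_indices.add(rec.dssp_index)
        chain = chains.get(rec.chain_id)
        if chain is None:
            chain = ChainRecord(chain_id=rec.chain_id)
            chains[rec.chain_id] = chain
            order.append(rec.chain_id)
        elif pending_break and rec.chain_id == last_chain:
            chain.break_positions.append(len(chain.residues))
        chain.residues.append(rec)
        last_chain = rec.chain_id
        pending_break = False

    for chain in chains.values():
        for rec in chain.residues:
            for bp in (rec.bp1, rec.bp2):
                if bp != 0 and bp not in seen_indices:
                    raise DSSPParseError(
                        f"residue {rec.dssp_index} references bridge partner "
                        f"{bp}, which is not in the file"
                    )
    return [chains[c] for c in order]


def filter_chains(
    chains: list[ChainRecord], policy: FilterPolicy = FilterPolicy()
) -> tuple[list[ChainRecord], list[tuple[str, str]]]:
    """Apply chain-level retention criteria.

    Returns the retained chains (order preserved) and a rejection log of
    ``(chain_id, reason)`` tuples.  No residue is dropped silently: a chain
    is either kept whole or rejected whole with its reason recorded.
    """
    retained: list[ChainRecord] = []
    rejections: list[tuple[str, str]] = []
    for chain in chains:
        if policy.reject_nonstandard and any(
            r.amino_acid == "X" for r in chain.residues
        ):
            rejections.append((chain.chain_id, REASON_NONSTANDARD))
            continue
        if policy.require_beta and not any(
            r.ss_state == "E" for r in chain.residues
        ):
            rejections.append((chain.chain_id, REASON_NO_BETA))
            continue
        retained.append(chain)
    return retained, rejections


_HEADER = """\
==== SECONDARY STRUCTURE DEFINITION (DSSP-format text written by strandpairs) ====
REFERENCE  W. KABSCH AND C.SANDER, BIOPOLYMERS 22 (1983) 2577-2637
  #  RESIDUE AA STRUCTURE BP1 BP2  ACC     N-H-->O    O-->H-N    N-H-->O    O-->H-N    TCO  KAPPA ALPHA  PHI   PSI    X-CA   Y-CA   Z-CA
"""


def _format_residue_line(rec: ResidueRecord) -> str:
    aa = rec.amino_acid
    if rec.disulfide:
        aa = "c"  # DSSP convention for SS-bonded cysteine
    return (
        f"{rec.dssp_index:5d}{rec.pdb_resnum:5d}{rec.insertion_code:1.1s}"
        f"{rec.chain_id:1.1s} {aa:1.1s}  {rec.ss_state:1.1s}"
        f"      {rec.bridge_label1:1.1s}{rec.bridge_label2:1.1s}"
        f"{rec.bp1:4d}{rec.bp2:4d}{rec.sheet_label:1.1s}   0"
    )


def emit_dssp(chains: list[ChainRecord]) -> str:
    """Write chains back to DSSP-format text.

    The output round-trips through :func:`parse_dssp` to records equal on
    every parsed field; columns this package does not read (accessibility,
    H-bond energies, angles, coordinates) are padded.  Chain breaks are
    written as ``!`` lines.  Records violating the DSSP-index or
    bridge-partner invariants are refused.
    """
    all_indices: set[int] = set()
    for chain in chains:
        for rec in chain.residues:
            if rec.dssp_index > 99999:
                raise ValueError(
                    f"dssp_index {rec.dssp_index} exceeds the 5-column index field"
                )
            if rec.bp1 > 9999 or rec.bp2 > 9999:
                raise ValueError(
                    f"dssp_index {rec.dssp_index}: bridge partner exceeds the "
                    "4-column BP field; split the data over several files"
                )
            all_indices.add(rec.dssp_index)
    lines = [_HEADER.rstrip("\n")]
    last_index = 0
    for chain in chains:
        breaks = set(chain.break_positions)
        for pos, rec in enumerate(chain.residues):
            if rec.dssp_index <= last_index:
                raise ValueError(
                    f"dssp_index {rec.dssp_index} not strictly increasing"
                )
            for bp in (rec.bp1, rec.bp2):
                if bp != 0 and bp not in all_indices:
                    raise ValueError(
                        f"dssp_index {rec.dssp_index}: bridge partner {bp} "
                        "not present among emitted residues"
                    )
            if pos in breaks and pos > 0:
                # Break line consumes an index between the flanking residues;
                # renumbering is the caller's job, so indices must leave room.
                if rec.dssp_index - last_index < 2:
                    raise ValueError(
                        f"no room for break line before dssp_index {rec.dssp_index}"
                    )
                lines.append(f"{last_index + 1:5d}        !              0   0")
            lines.append(_format_residue_line(rec))
            last_index = rec.dssp_index
    return "\n".join(lines) + "\n"


def renumber(chains: list[ChainRecord]) -> list[ChainRecord]:
    """Reassign DSSP indices sequentially across chains, leaving a gap at
    each recorded chain break so :func:`emit_dssp` can place break lines.

    Bridge-partner references are remapped consistently.  Useful when
    assembling synthetic chains from fragments.
    """
    mapping: dict[int, int] = {}
    nxt = 1
    for chain in chains:
        breaks = set(chain.break_positions)
        for pos, rec in enumerate(chain.residues):
            if pos in breaks and pos > 0:
                nxt += 1
            mapping[rec.dssp_index] = nxt
            nxt += 1
    out: list[ChainRecord] = []
    for chain in chains:
        new_res = [
            replace(
                rec,
                dssp_index=mapping[rec.dssp_index],
                bp1=mapping.get(rec.bp1, 0),
                bp2=mapping.get(rec.bp2, 0),
            )
            for rec in chain.residues
        ]
        out.append(
            ChainRecord(
                chain_id=chain.chain_id,
                residues=new_res,
                break_positions=list(chain.break_positions),
            )
        )
    return out
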