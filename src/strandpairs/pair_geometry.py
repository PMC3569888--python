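"""Beta-strand extraction, pair enumeration and registration decomposition.

A beta-strand is a maximal run of residues in the extended state ('E');
isolated single bridges ('B') are not strands.  Two strands form a pair
when at least one residue of one lists a residue of the other as a bridge
partner.  The pair's registration is decomposed into

    PL   length of the common paired part (bridged residues),
    Et1  terminal extension of strand 1  = SL1 - PL,
    Et2  terminal extension of strand 2  = SL2 - PL,
    EL   whole length of the pairing     = PL + Et1 + Et2,

where SL1, SL2 are the strand lengths.  Pairs whose bridged residues are
not one contiguous block per strand, or whose bridged-residue counts differ
between the strands, are flagged as beta-bulged; bulged pairs are excluded
from summary statistics by default.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

from strandpairs.dssp_io import ChainRecord, ResidueRecord

logger = logging.getLogger(__name__)

PARALLEL = "parallel"
ANTIPARALLEL = "antiparallel"


@dataclass
class BetaStrand:
    """A maximal run of 'E' residues in one chain."""

    chain_id: str
    residues: list[int]  # consecutive dssp_index values
    sheet_label: str = " "
    strand_ordinal: int = 0  # 1-based order of first residue along the chain

    @property
    def length(self) -> int:
        return len(self.residues)

    @property
    def start(self) -> int:
        return self.residues[0]

    @property
    def end(self) -> int:
        return self.residues[-1]

    def position_of(self, dssp_index: int) -> int:
        """0-based N-to-C position of a residue within the strand."""
        return self.residues.index(dssp_index)


@dataclass
class StrandPair:
    """Two adjacent strands with their registration decomposition.

    ``strand1`` is the strand earlier along the sequence (smaller ordinal;
    for interchain pairs the smaller ``(chain_id, ordinal)``).
    ``bridged_map`` lists the bridge links as ``(dssp_index in strand1,
    dssp_index in strand2)``, ordered along strand 1.
    """

    strand1: BetaStrand
    strand2: BetaStrand
    bridged_map: list[tuple[int, int]] = field(default_factory=list)
    orientation: str = ANTIPARALLEL
    SL1: int = 0
    SL2: int = 0
    PL: int = 0
    Et1: int = 0
    Et2: int = 0
    EL: int = 0
    bulged: bool = False

    @property
    def interchain(self) -> bool:
        return self.strand1.chain_id != self.strand2.chain_id

    @property
    def sheet_label(self) -> str:
        return self.strand1.sheet_label


@dataclass
class SheetGraph:
    """The strands of one sheet and the adjacent-strand pairs among them.

    ``bifurcated`` flags strands participating in more than two pairs,
    which happens in bifurcated (branched) sheets; a simple ladder gives
    every strand at most two neighbours.
    """

    sheet_label: str
    strands: list[BetaStrand]
    pairs: list[StrandPair]
    bifurcated: list[BetaStrand] = field(default_factory=list)


def extract_strands(chain: ChainRecord) -> list[BetaStrand]:
    """Return the beta-strands of a chain: maximal runs of ss_state 'E',
    split at chain breaks (and at any DSSP-index discontinuity).

    Single-residue 'E' runs count as strands; 'B' (isolated bridge) never
    does.  Strands are numbered 1.. by their N-terminal position.
    """
    strands: list[BetaStrand] = []
    breaks = set(chain.break_positions)
    run: list[ResidueRecord] = []

    def flush() -> None:
        if run:
            label = next(
                (r.sheet_label for r in run if r.sheet_label != " "), " "
            )
            strands.append(
                BetaStrand(
                    chain_id=chain.chain_id,
                    residues=[r.dssp_index for r in run],
                    sheet_label=label,
                )
            )
            run.clear()

    prev_index: int | None = None
    for pos, rec in enumerate(chain.residues):
        discontinuous = pos in breaks or (
            prev_index is not None and rec.dssp_index - prev_index > 1
        )
        if rec.ss_state != "E" or discontinuous:
            flush()
        if rec.ss_state == "E":
            run.append(rec)
        prev_index = rec.dssp_index
    flush()
    for i, s in enumerate(strands, start=1):
        s.strand_ordinal = i
    return strands


def _strand_sort_key(s: BetaStrand) -> tuple[str, int]:
    return (s.chain_id, s.strand_ordinal)


def classify_orientation(pair: StrandPair) -> str:
    """Classify a pair as parallel or antiparallel from its bridge links.

    With two or more links, the direction in which the partner index moves
    along strand 1 decides: increasing is parallel, decreasing
    antiparallel.  A single-link pair is decided by the ladder-label case
    DSSP recorded for that bridge (lowercase parallel, uppercase
    antiparallel); if no label is available the pair is classified
    antiparallel — the majority class — with a warning.  A non-monotonic
    progression marks the pair bulged and takes the majority direction.
    """
    links = sorted(
        pair.bridged_map, key=lambda ab: pair.strand1.position_of(ab[0])
    )
    if len(links) >= 2:
        partner_pos = [pair.strand2.position_of(b) for _, b in links]
        ups = sum(1 for x, y in zip(partner_pos, partner_pos[1:]) if y > x)
        downs = sum(1 for x, y in zip(partner_pos, partner_pos[1:]) if y < x)
        if ups and downs:
            pair.bulged = True
        if ups != downs:
            return PARALLEL if ups > downs else ANTIPARALLEL
        # fully ambiguous (e.g. duplicated partners); fall through to labels
    return _orientation_from_labels(pair, links)


def _orientation_from_labels(
    pair: StrandPair, links: list[tuple[int, int]]
) -> str:
    records = getattr(pair, "_records", None)
    if records is not None:
        for a, b in links:
            rec = records.get(a)
            if rec is None:
                continue
            for bp, lbl in ((rec.bp1, rec.bridge_label1), (rec.bp2, rec.bridge_label2)):
                if bp == b and lbl.isalpha():
                    return PARALLEL if lbl.islower() else ANTIPARALLEL
    logger.warning(
        "pair %s/%d-%s/%d: orientation indeterminate, defaulting to antiparallel",
        pair.strand1.chain_id,
        pair.strand1.strand_ordinal,
        pair.strand2.chain_id,
        pair.strand2.strand_ordinal,
    )
    return ANTIPARALLEL


def compute_registration(pair: StrandPair) -> StrandPair:
    """Fill SL1/SL2/PL/Et1/Et2/EL and the bulge flag from ``bridged_map``.

    PL counts distinct bridged residues (a residue bridging twice into the
    neighbour strand is counted once).  The pair is bulged when the bridged
    residues are non-contiguous in either strand or the two distinct counts
    differ; a bulged pair's PL is the smaller of the two counts.
    """
    if not pair.bridged_map:
        raise ValueError("cannot compute registration of a pair with no bridges")
    set1 = {a for a, _ in pair.bridged_map}
    set2 = {b for _, b in pair.bridged_map}
    pos1 = sorted(pair.strand1.position_of(a) for a in set1)
    pos2 = sorted(pair.strand2.position_of(b) for b in set2)
    contiguous = (pos1[-1] - pos1[0] + 1 == len(pos1)) and (
        pos2[-1] - pos2[0] + 1 == len(pos2)
    )
    if not contiguous or len(set1) != len(set2):
        pair.bulged = True
    pair.PL = min(len(set1), len(set2))
    pair.SL1 = pair.strand1.length
    pair.SL2 = pair.strand2.length
    pair.Et1 = pair.SL1 - pair.PL
    pair.Et2 = pair.SL2 - pair.PL
    pair.EL = pair.PL + pair.Et1 + pair.Et2
    return pair


def enumerate_pairs(
    strands: list[BetaStrand],
    records: dict[int, ResidueRecord],
) -> list[StrandPair]:
    """Enumerate adjacent strand pairs via the bridge-partner columns.

    Strands s, t pair when at least one residue of s lists a residue of t
    as bp1 or bp2.  Each unordered pair is reported once, with the
    registration decomposition and orientation computed.  A bridge partner
    pointing at a non-'E' residue (an isolated bridge or a mislabelled
    line) is ignored with a warning.

    Parameters
    ----------
    strands
        Strands from :func:`extract_strands`, possibly over several chains.
    records
        Residue lookup by dssp_index covering every strand residue.
    """
    owner: dict[int, BetaStrand] = {}
    for s in strands:
        for idx in s.residues:
            owner[idx] = s
    links: dict[tuple[int, int], set[tuple[int, int]]] = {}
    strand_key = {id(s): i for i, s in enumerate(sorted(strands, key=_strand_sort_key))}
    by_key = {i: s for s, i in zip(sorted(strands, key=_strand_sort_key), strand_key.values())}

    for s in strands:
        for idx in s.residues:
            rec = records.get(idx)
            if rec is None:
                continue
            for bp in (rec.bp1, rec.bp2):
                if bp == 0:
                    continue
                t = owner.get(bp)
                if t is None:
                    partner = records.get(bp)
                    if partner is not None and partner.ss_state != "E":
                        logger.warning(
                            "residue %d: bridge partner %d is not in a strand "
                            "(ss %r); link ignored",
                            idx,
                            bp,
                            partner.ss_state,
                        )
                    continue
                if t is s:
                    continue
                k1, k2 = strand_key[id(s)], strand_key[id(t)]
                key = (min(k1, k2), max(k1, k2))
                link = (idx, bp) if k1 < k2 else (bp, idx)
                links.setdefault(key, set()).add(link)

    pairs: list[StrandPair] = []
    for (k1, k2), linkset in sorted(links.items()):
        s1, s2 = by_key[k1], by_key[k2]
        pair = StrandPair(strand1=s1, strand2=s2)
        pair.bridged_map = sorted(linkset, key=lambda ab: s1.position_of(ab[0]))
        pair._records = records  # for single-bridge ladder-label lookup
        compute_registration(pair)
        pair.orientation = classify_orientation(pair)
        del pair._records
        pairs.append(pair)
    return pairs


def build_sheets(
    strands: list[BetaStrand], pairs: list[StrandPair]
) -> list[SheetGraph]:
    """Group strands and pairs into per-sheet partnership graphs.

    Sheets are connected components of the pairing graph; the DSSP sheet
    label of the component's first strand names the sheet.  Strands with
    more than two partners are flagged as bifurcation points.
    """
    import networkx as nx

    g = nx.Graph()
    for s in strands:
        g.add_node(_strand_sort_key(s), strand=s)
    for p in pairs:
        g.add_edge(
            _strand_sort_key(p.strand1), _strand_sort_key(p.strand2), pair=p
        )
        g.nodes[_strand_sort_key(p.strand1)].setdefault("strand", p.strand1)
        g.nodes[_strand_sort_key(p.strand2)].setdefault("strand", p.strand2)
    sheets: list[SheetGraph] = []
    for comp in nx.connected_components(g):
        comp_strands = sorted(
            (g.nodes[n]["strand"] for n in comp), key=_strand_sort_key
        )
        if len(comp_strands) == 1 and g.degree(_strand_sort_key(comp_strands[0])) == 0:
            continue  # unpaired strand: not part of any sheet graph
        comp_pairs = [
            g.edges[e]["pair"] for e in g.subgraph(comp).edges
        ]
        comp_pairs.sort(key=lambda p: _strand_sort_key(p.strand1))
        bifurcated = [s for s in comp_strands if g.degree(_strand_sort_key(s)) > 2]
        sheets.append(
            SheetGraph(
                sheet_label=comp_strands[0].sheet_label,
                strands=comp_strands,
                pairs=comp_pairs,
                bifurcated=bifurcated,
            )
        )
    sheets.sort(key=lambda sh: _strand_sort_key(sh.strands[0]))
    return sheets


def pairs_from_chains(chains: list[ChainRecord]) -> list[StrandPair]:
    """Convenience: extract strands from every chain and enumerate all
    pairs (including interchain ones) in one step."""
    strands: list[BetaStrand] = []
    records: dict[int, ResidueRecord] = {}
    for chain in chains:
        strands.extend(extract_strands(chain))
        for rec in chain.residues:
            records[rec.dssp_index] = rec
    return enumerate_pairs(strands, records)
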