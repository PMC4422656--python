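"""Salt-bridge detection/classification and L4-loop position typing.

The binding sites of human galectin-1, the galectin-3 CRD and galectin-7
each carry an Arg-Asp/Glu-Glu-Arg quartet behind the sugar-binding
residues. Each basic-acidic pair is classified geometrically:

* bidentate: a two-pronged ("fork-fork") arrangement, i.e. at least two
  sidechain N-O contacts within the cutoff that use two *different*
  nitrogen atoms and two *different* carboxylate oxygens;
* monodentate: every other bridged arrangement (single N-O contact, or
  several contacts sharing one nitrogen or one oxygen).

The default cutoff is 4.0 A on sidechain nitrogens (Arg NE/NH1/NH2,
Lys NZ) to carboxylate oxygens (Asp OD1/OD2, Glu OE1/OE2).

The acidic quartet member sits on the L4 loop between beta-strands S4 and
S5; its position class (internal vs terminal) together with the loop
length separates the LN1-preferring short-loop architecture from the
LN2-preferring long-loop one.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .errors import AnnotationError, ResidueLookupError
from .structure_io import CorrespondenceMap, Structure

DEFAULT_SALTBRIDGE_CUTOFF = 4.0

BASIC_SIDECHAIN_N = {"ARG": ("NE", "NH1", "NH2"), "LYS": ("NZ",)}
ACIDIC_SIDECHAIN_O = {"ASP": ("OD1", "OD2"), "GLU": ("OE1", "OE2")}


@dataclass(frozen=True)
class SaltBridge:
    basic_residue: tuple[str, str, int]  # (chain, resname, seq)
    acidic_residue: tuple[str, str, int]
    no_pairs: tuple[tuple[str, str, float], ...]  # (N atom, O atom, dist)
    geometry_class: str  # "monodentate" | "bidentate"


def classify_pairs(no_pairs) -> str:
    """Classify a set of qualifying N-O contact pairs.

    Bidentate iff two pairs exist with distinct N and distinct O atoms
    (fork-fork); single-atom multi-contacts stay monodentate.
    """
    pairs = list(no_pairs)
    for i, (n1, o1, _) in enumerate(pairs):
        for n2, o2, _ in pairs[i + 1:]:
            if n1 != n2 and o1 != o2:
                return "bidentate"
    return "monodentate"


def find_salt_bridges(
    s: Structure, cutoff: float = DEFAULT_SALTBRIDGE_CUTOFF
) -> list[SaltBridge]:
    """All Arg/Lys-Asp/Glu residue pairs with >= 1 sidechain N-O contact
    within ``cutoff``, each with its geometry class."""
    basics: dict[tuple[str, str, int], dict[str, np.ndarray]] = {}
    acidics: dict[tuple[str, str, int], dict[str, np.ndarray]] = {}
    for a in s.atoms:
        if a.residue_name in BASIC_SIDECHAIN_N and (
            a.atom_name in BASIC_SIDECHAIN_N[a.residue_name]
        ):
            basics.setdefault((a.chain_id, a.residue_name, a.residue_seq), {})[
                a.atom_name
            ] = a.xyz
        elif a.residue_name in ACIDIC_SIDECHAIN_O and (
            a.atom_name in ACIDIC_SIDECHAIN_O[a.residue_name]
        ):
            acidics.setdefault((a.chain_id, a.residue_name, a.residue_seq), {})[
                a.atom_name
            ] = a.xyz
    bridges = []
    for bkey, natoms in sorted(basics.items()):
        for akey, oatoms in sorted(acidics.items()):
            pairs = []
            for nname, nxyz in natoms.items():
                for oname, oxyz in oatoms.items():
                    d = float(np.linalg.norm(nxyz - oxyz))
                    if d <= cutoff:
                        pairs.append((nname, oname, round(d, 2)))
            if pairs:
                pairs.sort()
                bridges.append(
                    SaltBridge(
                        basic_residue=bkey,
                        acidic_residue=akey,
                        no_pairs=tuple(pairs),
                        geometry_class=classify_pairs(pairs),
                    )
                )
    return bridges


# ---------------------------------------------------------------------------
# L4 loop annotation and classification

L4_SHORT_THRESHOLD = 6  # loops up to this many residues count as short


@dataclass(frozen=True)
class L4Annotation:
    """S4-S5 loop boundaries plus the acidic residue position.

    ``l4_start``..``l4_end`` are the loop residue numbers (inclusive);
    ``s5_start`` is the first residue of strand S5.
    """

    l4_start: int
    l4_end: int
    acidic_seq: int
    s5_start: int | None = None


# Built-in annotations for the three structures, derived from the strand
# spans implied by the conserved contact residues (His/Asn/Arg on S4,
# Val/Asn on S5). Overridable by the caller.
BUILTIN_L4 = {
    "hGal1": L4Annotation(l4_start=49, l4_end=58, acidic_seq=54, s5_start=59),
    "hGal3": L4Annotation(l4_start=163, l4_end=171, acidic_seq=165, s5_start=172),
    "hGal7": L4Annotation(l4_start=54, l4_end=58, acidic_seq=58, s5_start=59),
}


@dataclass(frozen=True)
class L4Class:
    position: str  # "internal" | "terminal"
    length: int
    length_class: str  # "short" | "long"
    group: str  # "hGal7-group" | "hGal7-like/Gal2-like" | "hGal1/3-like"


def classify_l4(
    annotation: L4Annotation, short_threshold: int = L4_SHORT_THRESHOLD
) -> L4Class:
    """Classify the acidic residue's position within the S4-S5 loop.

    Terminal iff the acidic residue occupies the last loop position or the
    first S5 position; otherwise internal. The group label combines the
    position with the loop-length class: a terminal acid marks the
    LN1-preferring short-loop architecture (hGal7 group), an internal acid
    in a short loop the hGal7-like/Gal2-like subgroup, and an internal
    acid in a long loop the hGal1/3-like architecture.
    """
    a = annotation
    if a.l4_end < a.l4_start:
        raise AnnotationError("l4_end precedes l4_start")
    s5_start = a.s5_start if a.s5_start is not None else a.l4_end + 1
    if not (a.l4_start <= a.acidic_seq <= s5_start):
        raise AnnotationError(
            f"acidic residue {a.acidic_seq} outside region "
            f"[{a.l4_start}, {s5_start}]"
        )
    position = "terminal" if a.acidic_seq in (a.l4_end, s5_start) else "internal"
    length = a.l4_end - a.l4_start + 1
    length_class = "short" if length <= short_threshold else "long"
    if position == "terminal":
        group = "hGal7-group"
    elif length_class == "short":
        group = "hGal7-like/Gal2-like"
    else:
        group = "hGal1/3-like"
    return L4Class(position=position, length=length, length_class=length_class,
                   group=group)


# ---------------------------------------------------------------------------
# the quartet network


@dataclass
class SaltBridgeNetwork:
    galectin: str
    quartet: list[tuple[str, int]]  # (resname, seq) in sequence order
    bridges: list[SaltBridge]
    l4: L4Class

    def bridge_between(self, seq_a: int, seq_b: int) -> SaltBridge | None:
        for b in self.bridges:
            seqs = {b.basic_residue[2], b.acidic_residue[2]}
            if seqs == {seq_a, seq_b}:
                return b
        return None


def extract_network(
    s: Structure,
    cmap: CorrespondenceMap,
    galectin: str,
    cutoff: float = DEFAULT_SALTBRIDGE_CUTOFF,
    l4_annotation: L4Annotation | None = None,
) -> SaltBridgeNetwork:
    """Locate the Arg-Asp/Glu-Glu-Arg quartet and classify its bridges.

    Raises if a quartet residue is absent from the structure (naming it).
    Only bridges whose two members both belong to the quartet are
    reported.
    """
    quartet = cmap.network_quartet(galectin)
    present = {(name, seq) for _chain, name, seq in s.residues()}
    for name, seq in quartet:
        if (name, seq) not in present:
            raise ResidueLookupError(
                f"quartet residue {name}{seq} missing from '{s.id}'"
            )
    quartet_seqs = {seq for _, seq in quartet}
    bridges = [
        b
        for b in find_salt_bridges(s, cutoff)
        if b.basic_residue[2] in quartet_seqs and b.acidic_residue[2] in quartet_seqs
    ]
    ann = l4_annotation or BUILTIN_L4[galectin]
    return SaltBridgeNetwork(
        galectin=galectin,
        quartet=quartet,
        bridges=bridges,
        l4=classify_l4(ann),
    )
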