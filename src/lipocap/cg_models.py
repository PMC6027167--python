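"""Coarse-grained bead types, molecular topologies and the chitosan sequence
grammar.

The mesoscopic mapping uses nine bead types:

===== ==================== ==========================================
name  role                 represents
===== ==================== ==========================================
L1    head                 lecithin phosphocholine head group
L2    neck                 lecithin glycerol/ester linker
L3    tail                 lecithin acyl-chain segment
C1    head                 capsaicin vanillyl (aromatic/polar) group
C2    neck                 capsaicin amide linker
C3    tail                 capsaicin hydrocarbon tail
G     glucosamine          chitosan d-glucosamine (deacetylated) unit
A     acetyl-glucosamine   chitosan N-acetyl-d-glucosamine unit
W     solvent              water (several molecules per bead)
===== ==================== ==========================================

Chitosan chains are specified in a compact block notation, e.g.
``[-GlucNA-[GlcN]3-GlucNA-[GlcN]3-GlucNA-GlcN-]5`` for a 50-mer with acetyl
fraction 0.30.  :func:`parse_sequence_spec` expands such strings into explicit
monomer lists; :func:`builtin_sequence` provides the two reference 50-mers S1
(quasi-random acetylation pattern) and S2 (blocky pattern), both at 30%
N-acetylation.
"""

from __future__ import annotations

import re
from dataclasses import dataclass, field

__all__ = [
    "BEAD_TYPES",
    "BEAD_ROLES",
    "BeadSpec",
    "ChitosanSequence",
    "MoleculeTopology",
    "bead_index",
    "parse_sequence_spec",
    "degree_of_acetylation",
    "builtin_sequence",
    "lecithin_topology",
    "capsaicin_topology",
    "chitosan_topology",
]

#: Canonical bead-type ordering used throughout the package (interaction
#: matrices, engine type codes, trajectory species columns).
BEAD_TYPES: tuple[str, ...] = ("L1", "L2", "L3", "C1", "C2", "C3", "G", "A", "W")

BEAD_ROLES: dict[str, str] = {
    "L1": "head",
    "L2": "neck",
    "L3": "tail",
    "C1": "head",
    "C2": "neck",
    "C3": "tail",
    "G": "glucosamine",
    "A": "acetyl-glucosamine",
    "W": "solvent",
}


def bead_index(name: str) -> int:
    """Integer type code of a bead name in the canonical ordering."""
    try:
        return BEAD_TYPES.index(name)
    except ValueError:
        raise KeyError(f"unknown bead type {name!r}; expected one of {BEAD_TYPES}") from None


@dataclass(frozen=True)
class BeadSpec:
    """One coarse-grained bead type.

    Parameters
    ----------
    name:
        One of :data:`BEAD_TYPES`.
    role:
        Functional role (head / neck / tail / glucosamine /
        acetyl-glucosamine / solvent).
    mass:
        Reduced mass; the conventional DPD choice is 1 for every bead.
    """

    name: str
    role: str = ""
    mass: float = 1.0

    def __post_init__(self) -> None:
        if self.name not in BEAD_TYPES:
            raise ValueError(f"unknown bead name {self.name!r}")
        if self.mass <= 0:
            raise ValueError("bead mass must be positive")
        if not self.role:
            object.__setattr__(self, "role", BEAD_ROLES[self.name])


@dataclass(frozen=True)
class ChitosanSequence:
    """An explicit chitosan monomer sequence over {G, A}.

    G = d-glucosamine (deacetylated), A = N-acetyl-d-glucosamine.  The acetyl
    fraction count(A)/length is the degree of N-acetylation.
    """

    monomers: tuple[str, ...]

    def __post_init__(self) -> None:
        if len(self.monomers) == 0:
            raise ValueError("chitosan sequence must be non-empty")
        bad = set(self.monomers) - {"G", "A"}
        if bad:
            raise ValueError(f"invalid monomer symbols {sorted(bad)}; only G and A allowed")

    def __len__(self) -> int:
        return len(self.monomers)

    @property
    def acetyl_fraction(self) -> float:
        return self.monomers.count("A") / len(self.monomers)

    def to_string(self) -> str:
        """Serialize as a plain G/A string, e.g. ``\"AGGGAGGGAG\"``."""
        return "".join(self.monomers)

    @classmethod
    def from_string(cls, s: str) -> "ChitosanSequence":
        return cls(tuple(s))


@dataclass(frozen=True)
class MoleculeTopology:
    """Bead composition and intramolecular bonding of one molecule.

    ``bonds`` are 0-based index pairs into ``beads``.  Invariants enforced at
    construction: indices valid, no self-bonds or duplicates, bond graph
    connected.  Bonds are stored with the lower index first; for every bead
    except bead 0 there is at least one bond to a lower-indexed bead, so a
    molecule can be unwrapped across periodic boundaries in a single
    index-ordered pass.
    """

    species: str
    beads: tuple[str, ...]
    bonds: tuple[tuple[int, int], ...] = field(default_factory=tuple)

    def __post_init__(self) -> None:
        n = len(self.beads)
        if n == 0:
            raise ValueError("topology must contain at least one bead")
        for b in self.beads:
            if b not in BEAD_TYPES:
                raise ValueError(f"unknown bead type {b!r}")
        norm = []
        seen = set()
        for i, j in self.bonds:
            if i == j:
                raise ValueError(f"self-bond on bead {i}")
            if not (0 <= i < n and 0 <= j < n):
                raise ValueError(f"bond ({i},{j}) out of range for {n} beads")
            pair = (min(i, j), max(i, j))
            if pair in seen:
                raise ValueError(f"duplicate bond {pair}")
            seen.add(pair)
            norm.append(pair)
        object.__setattr__(self, "bonds", tuple(sorted(norm)))
        if n > 1 and not self._connected():
            raise ValueError("bond graph is not connected")

    def _connected(self) -> bool:
        adj: dict[int, list[int]] = {i: [] for i in range(len(self.beads))}
        for i, j in self.bonds:
            adj[i].append(j)
            adj[j].append(i)
        seen = {0}
        stack = [0]
        while stack:
            for k in adj[stack.pop()]:
                if k not in seen:
                    seen.add(k)
                    stack.append(k)
        return len(seen) == len(self.beads)

    @property
    def n_beads(self) -> int:
        return len(self.beads)

    @property
    def n_bonds(self) -> int:
        return len(self.bonds)

    def to_config_block(self) -> dict:
        """Plain-data representation for structured config files."""
        return {
            "species": self.species,
            "beads": list(self.beads),
            "bonds": [list(b) for b in self.bonds],
        }

    @classmethod
    def from_config_block(cls, block: dict) -> "MoleculeTopology":
        return cls(
            species=block["species"],
            beads=tuple(block["beads"]),
            bonds=tuple((int(i), int(j)) for i, j in block.get("bonds", [])),
        )


# --------------------------------------------------------------------------
# sequence grammar
# --------------------------------------------------------------------------

_TOKEN_RE = re.compile(r"GlucNA|GlcN|G|A|\[|\]|\d+")

# printed block notation decorates tokens with various dash glyphs; strip all
_DASHES = "-−–—­ \t\n"


def _tokenize(spec: str) -> list[str]:
    cleaned = "".join(ch for ch in spec if ch not in _DASHES)
    tokens: list[str] = []
    pos = 0
    while pos < len(cleaned):
        m = _TOKEN_RE.match(cleaned, pos)
        if m is None:
            raise ValueError(f"unknown token at {cleaned[pos:pos+8]!r} in sequence spec")
        tokens.append(m.group(0))
        pos = m.end()
    return tokens


def parse_sequence_spec(spec: str) -> ChitosanSequence:
    """Expand a block-notation chitosan spec into an explicit monomer list.

    Grammar: a sequence of items, where an item is a monomer token
    (``GlucNA``/``A`` for N-acetyl-glucosamine, ``GlcN``/``G`` for
    glucosamine) or a bracketed sub-sequence, optionally followed by a
    positive integer repeat count that applies to the immediately preceding
    item.  Dashes between tokens are decorative and ignored.  Nesting is
    unrestricted.

    Examples
    --------
    >>> len(parse_sequence_spec("[GlcN]4"))
    4
    >>> parse_sequence_spec("[-GlucNA-[GlcN]3-]2").to_string()
    'AGGGAGGG'
    """
    tokens = _tokenize(spec)

    def parse_items(pos: int, depth: int) -> tuple[list[str], int]:
        out: list[str] = []
        last: list[str] | None = None
        while pos < len(tokens):
            tok = tokens[pos]
            if tok == "[":
                group, pos = parse_items(pos + 1, depth + 1)
                if pos >= len(tokens) or tokens[pos] != "]":
                    raise ValueError("unbalanced brackets in sequence spec")
                pos += 1
                last = group
                out.extend(group)
            elif tok == "]":
                if depth == 0:
                    raise ValueError("unbalanced brackets in sequence spec")
                return out, pos
            elif tok.isdigit():
                count = int(tok)
                if count <= 0:
                    raise ValueError(f"repeat count must be positive, got {count}")
                if last is None:
                    raise ValueError("repeat count with no preceding group or token")
                out.extend(last * (count - 1))
                last = None
                pos += 1
            else:
                mono = "A" if tok in ("GlucNA", "A") else "G"
                last = [mono]
                out.append(mono)
                pos += 1
        if depth != 0:
            raise ValueError("unbalanced brackets in sequence spec")
        return out, pos

    monomers, _ = parse_items(0, 0)
    if not monomers:
        raise ValueError("empty sequence spec")
    return ChitosanSequence(tuple(monomers))


def degree_of_acetylation(seq: ChitosanSequence) -> float:
    """Acetyl fraction count(A)/length of a chitosan sequence, in [0, 1].

    This is the degree of N-acetylation; the degree of deacetylation is its
    complement (fraction of G units).
    """
    return seq.acetyl_fraction


#: Block-notation specs of the two reference 50-mer acetylation patterns.
#: S1 distributes the acetyl units quasi-uniformly along the chain; S2 groups
#: them into blocks.  Both have acetyl fraction exactly 0.30.
BUILTIN_SEQUENCE_SPECS: dict[str, str] = {
    "S1": "[-GlucNA-[GlcN]3-GlucNA-[GlcN]3-GlucNA-GlcN-]5",
    "S2": "[-[GlucNA]4-[GlcN]9]3-[GlucNA]3-[GlcN]8",
}


def builtin_sequence(name: str) -> ChitosanSequence:
    """Return one of the reference chitosan 50-mers, ``\"S1\"`` or ``\"S2\"``."""
    try:
        spec = BUILTIN_SEQUENCE_SPECS[name]
    except KeyError:
        raise ValueError(f"unknown builtin sequence {name!r}; choose from S1, S2") from None
    return parse_sequence_spec(spec)


# --------------------------------------------------------------------------
# molecule topologies
# --------------------------------------------------------------------------

def lecithin_topology(n_tails: int = 2, beads_per_tail: int = 3) -> MoleculeTopology:
    """Coarse-grained lecithin: head L1 - neck L2 - ``n_tails`` acyl chains of L3.

    The default (two tails of three beads, eight beads total) reflects the two
    acyl chains of a C42 phosphatidylcholine.  Bead order: L1, L2, then each
    tail's L3 beads consecutively; the neck is the branch point.
    """
    if n_tails < 1 or beads_per_tail < 1:
        raise ValueError("n_tails and beads_per_tail must be >= 1")
    beads: list[str] = ["L1", "L2"]
    bonds: list[tuple[int, int]] = [(0, 1)]
    for _ in range(n_tails):
        prev = 1  # tails attach to the neck
        for _ in range(beads_per_tail):
            beads.append("L3")
            bonds.append((prev, len(beads) - 1))
            prev = len(beads) - 1
    return MoleculeTopology("lecithin", tuple(beads), tuple(bonds))


def capsaicin_topology() -> MoleculeTopology:
    """Coarse-grained capsaicin: linear C1 (vanillyl) - C2 (amide) - C3 (tail)."""
    return MoleculeTopology("capsaicin", ("C1", "C2", "C3"), ((0, 1), (1, 2)))


def chitosan_topology(seq: ChitosanSequence) -> MoleculeTopology:
    """Linear chitosan chain, one bead (G or A) per monomer of ``seq``."""
    n = len(seq)
    bonds = tuple((i, i + 1) for i in range(n - 1))
    return MoleculeTopology("chitosan", seq.monomers, bonds)
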