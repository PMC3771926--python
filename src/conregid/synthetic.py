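"""Planted-domain synthetic protein datasets with ground truth.

The generator emulates the situations the pipeline must handle: families of
sequences sharing one conserved domain embedded in random flanks, remote
homologs (heavily mutated members whose pairwise similarity to the family
can fall below the connectivity threshold but that a profile search should
still recover), and multi-domain sequences carrying domains from several
distinct families — the chaining stressor.

Flanks and domain consensuses are drawn i.i.d. from a standard amino-acid
background composition; no low-complexity runs, phylogenies, or real
database domains are emulated.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .seqdata import AMINO_ACIDS, RegionAnnotation, Sequence

#: Robinson-Robinson style background amino-acid frequencies in
#: :data:`AMINO_ACIDS` order (A C D E F G H I K L M N P Q R S T V W Y).
BACKGROUND = np.array(
    [
        0.0787, 0.0151, 0.0535, 0.0668, 0.0397, 0.0696, 0.0229, 0.0591,
        0.0595, 0.0965, 0.0241, 0.0414, 0.0484, 0.0395, 0.0542, 0.0683,
        0.0541, 0.0673, 0.0110, 0.0303,
    ]
)
BACKGROUND = BACKGROUND / BACKGROUND.sum()


@dataclass(frozen=True)
class DomainModel:
    """A planted domain: an id and a consensus residue string."""

    id: str
    consensus: str

    def __post_init__(self) -> None:
        if not (25 <= len(self.consensus) <= 300):
            raise ValueError("domain consensus length must be in [25, 300]")


@dataclass
class GroundTruth:
    """Planted intervals per sequence and member sets per domain."""

    intervals: dict[str, list[tuple[str, int, int]]] = field(default_factory=dict)
    members: dict[str, set[str]] = field(default_factory=dict)

    def annotations(self) -> list[RegionAnnotation]:
        out = []
        for sid in sorted(self.intervals):
            for dom, start, end in self.intervals[sid]:
                out.append(RegionAnnotation(sid, start, end, dom))
        return out

    def family_partition(self) -> list[set[str]]:
        """Reference partition: connected components of the sequence x domain
        bipartite graph (multi-domain sequences link their families)."""
        import networkx as nx

        g = nx.Graph()
        for sid, ivs in self.intervals.items():
            g.add_node(("s", sid))
            for dom, _, _ in ivs:
                g.add_edge(("s", sid), ("d", dom))
        comps = []
        for comp in nx.connected_components(g):
            seqs = {name for kind, name in comp if kind == "s"}
            if seqs:
                comps.append(seqs)
        return sorted(comps, key=lambda c: (-len(c), sorted(c)))


def _draw(rng: np.random.Generator, length: int, composition: np.ndarray) -> str:
    idx = rng.choice(20, size=length, p=composition)
    return "".join(AMINO_ACIDS[i] for i in idx)


def make_domain(
    length: int,
    seed: int | np.random.Generator,
    domain_id: str = "D1",
    composition: np.ndarray = BACKGROUND,
) -> DomainModel:
    """A domain consensus of ``length`` drawn from ``composition``."""
    if not (25 <= length <= 300):
        raise ValueError("domain length must be in [25, 300]")
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    return DomainModel(domain_id, _draw(rng, length, composition))


def emit_member(
    model: DomainModel,
    mutation_rate: float,
    indel_rate: float,
    seed: int | np.random.Generator,
) -> tuple[str, list[int]]:
    """A mutated copy of a domain consensus.

    Point substitutions replace residues with a different random residue at
    ``mutation_rate`` per position; short indels (1-3 residues) occur at
    ``indel_rate`` per position.  Returns the emitted segment and, per
    emitted residue, the consensus position it derives from (-1 for
    insertions).
    """
    if not (0 <= mutation_rate <= 0.5 and 0 <= indel_rate <= 0.5):
        raise ValueError("rates must be in [0, 0.5]")
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    out: list[str] = []
    mapping: list[int] = []
    pos = 0
    consensus = model.consensus
    while pos < len(consensus):
        if indel_rate > 0 and rng.random() < indel_rate:
            size = int(rng.integers(1, 4))
            if rng.random() < 0.5:  # deletion
                pos += size
                continue
            for _ in range(size):  # insertion
                out.append(AMINO_ACIDS[int(rng.integers(0, 20))])
                mapping.append(-1)
        ch = consensus[pos]
        if rng.random() < mutation_rate:
            choices = [a for a in AMINO_ACIDS if a != ch]
            ch = choices[int(rng.integers(0, 19))]
        out.append(ch)
        mapping.append(pos)
        pos += 1
    return "".join(out), mapping


def generate_dataset(
    n_families: int = 6,
    members_per_family: int = 30,
    multi_domain_fraction: float = 0.1,
    remote_fraction: float = 0.15,
    flank_length_range: tuple[int, int] = (30, 150),
    seed: int = 0,
    domain_length_range: tuple[int, int] = (60, 120),
    mutation_rate: float = 0.08,
    remote_mutation_rate: float = 0.3,
    indel_rate: float = 0.01,
    domains_per_multi: tuple[int, int] = (2, 3),
) -> tuple[list[Sequence], GroundTruth]:
    """Generate a planted-domain dataset with ground truth.

    Each family contributes ``members_per_family`` sequences carrying its
    domain in random flanks; a ``multi_domain_fraction`` of all sequences
    additionally carries domains from 1-2 other families (2-3 domains
    total), and a ``remote_fraction`` of each family's members mutates at
    ``remote_mutation_rate``.  Fully deterministic per seed; every sequence
    lies in the 100-10000 length window.
    """
    if n_families < 1 or members_per_family < 1:
        raise ValueError("need at least one family and one member")
    if not (0 <= multi_domain_fraction <= 1 and 0 <= remote_fraction <= 1):
        raise ValueError("fractions must be in [0, 1]")
    rng = np.random.default_rng(seed)
    domains = [
        make_domain(
            int(rng.integers(domain_length_range[0], domain_length_range[1] + 1)),
            rng,
            domain_id=f"D{f + 1}",
        )
        for f in range(n_families)
    ]
    total = n_families * members_per_family
    n_multi = int(round(multi_domain_fraction * total))
    multi_ids = set(rng.choice(total, size=n_multi, replace=False).tolist())

    seqs: list[Sequence] = []
    gt = GroundTruth(members={d.id: set() for d in domains})
    serial = 0
    for f in range(n_families):
        n_remote = int(round(remote_fraction * members_per_family))
        remote_members = set(
            rng.choice(members_per_family, size=n_remote, replace=False).tolist()
        )
        for m in range(members_per_family):
            sid = f"seq{serial:04d}"
            rate = remote_mutation_rate if m in remote_members else mutation_rate
            carried = [f]
            if serial in multi_ids and n_families > 1:
                k = int(rng.integers(domains_per_multi[0], domains_per_multi[1] + 1))
                k = min(k, n_families)
                others = [g for g in range(n_families) if g != f]
                extra = rng.choice(len(others), size=k - 1, replace=False)
                carried += [others[int(e)] for e in sorted(extra)]
            parts: list[str] = []
            ivs: list[tuple[str, int, int]] = []
            pos = 0
            for dom_idx in carried:
                flank = _draw(
                    rng,
                    int(rng.integers(flank_length_range[0], flank_length_range[1] + 1)),
                    BACKGROUND,
                )
                parts.append(flank)
                pos += len(flank)
                segment, _ = emit_member(domains[dom_idx], rate, indel_rate, rng)
                parts.append(segment)
                ivs.append((domains[dom_idx].id, pos + 1, pos + len(segment)))
                gt.members[domains[dom_idx].id].add(sid)
                pos += len(segment)
            parts.append(
                _draw(
                    rng,
                    int(rng.integers(flank_length_range[0], flank_length_range[1] + 1)),
                    BACKGROUND,
                )
            )
            seqs.append(Sequence(sid, "".join(parts)))
            gt.intervals[sid] = ivs
            serial += 1
    return seqs, gt


def chaining_dataset(
    seed: int = 0,
    n_families: int = 3,
    members_per_family: int = 5,
    **kwargs,
) -> tuple[list[Sequence], GroundTruth]:
    """The chaining stressor topology: families sharing one multi-domain
    sequence that carries every family's domain.

    The extra sequence (id ``seqX``) is the only inter-family link, so the
    connectivity graph has the families as cliques joined at a single shared
    vertex.
    """
    seqs, gt = generate_dataset(
        n_families=n_families,
        members_per_family=members_per_family,
        multi_domain_fraction=0.0,
        remote_fraction=0.0,
        seed=seed,
        **kwargs,
    )
    rng = np.random.default_rng(seed + 1)
    # rebuild the domain models exactly as generate_dataset drew them
    gen_rng = np.random.default_rng(seed)
    dlr = kwargs.get("domain_length_range", (60, 120))
    domains = [
        make_domain(int(gen_rng.integers(dlr[0], dlr[1] + 1)), gen_rng, f"D{f + 1}")
        for f in range(n_families)
    ]
    mutation_rate = kwargs.get("mutation_rate", 0.08)
    parts: list[str] = []
    ivs: list[tuple[str, int, int]] = []
    pos = 0
    for dom in domains:
        flank = _draw(rng, int(rng.integers(30, 60)), BACKGROUND)
        parts.append(flank)
        pos += len(flank)
        segment, _ = emit_member(dom, mutation_rate, 0.01, rng)
        parts.append(segment)
        ivs.append((dom.id, pos + 1, pos + len(segment)))
        gt.members[dom.id].add("seqX")
        pos += len(segment)
    parts.append(_draw(rng, int(rng.integers(30, 60)), BACKGROUND))
    seqs.append(Sequence("seqX", "".join(parts)))
    gt.intervals["seqX"] = ivs
    return seqs, gt
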