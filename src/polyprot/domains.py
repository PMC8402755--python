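"""Domain/subdomain residue maps for PFV PR-RT and structure annotation.

The prototype foamy virus protease–reverse transcriptase is a single
751-residue chain comprising the protease (PR), a protease C-terminal
extension (PR-CTE) that anchors PR to the RT palm, the four polymerase
subdomains (fingers, palm, thumb, connection) and the RNase H domain.  The
default map partitions author numbers 1..751 into those seven groups, leaving
the short inter-domain linkers (368–377 between palm and thumb, 591–592
before RNase H) unassigned; feature sites (catalytic motifs, primer grip)
are annotations on top of the partition, not partition members.

Two maps ship with the package: :func:`default_pfv_map`, whose fingers
subdomain starts at 146 so that the partition is disjoint from PR-CTE
(101–145), and :func:`literal_pfv_map`, which keeps the fingers start at 144
as annotated in the structure and therefore overlaps PR-CTE — its validator
reports the overlap rather than silently resolving it.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

from .structure_io import AtomGroup, AtomRef, StructureModel

UNASSIGNED = "linker"

Range = tuple[int, int]


@dataclass
class DomainMap:
    """Named residue-range partition plus feature-site annotations.

    ``segments`` maps domain name -> list of inclusive author-number ranges;
    ``features`` maps feature name -> explicit residue list.  Overlaps
    *within* a domain are forbidden; overlaps *across* domains are reported
    by :meth:`validate` and resolved at annotation time by first-declared
    domain order (the resolution is deterministic and reported, never
    silent).
    """

    segments: dict[str, list[Range]]
    features: dict[str, list[int]] = field(default_factory=dict)
    unassigned_label: str = UNASSIGNED

    def __post_init__(self) -> None:
        for name, ranges in self.segments.items():
            covered: set[int] = set()
            for start, end in ranges:
                if start > end:
                    raise ValueError(f"domain {name!r}: range {start}-{end} inverted")
                rng = set(range(start, end + 1))
                if covered & rng:
                    raise ValueError(f"domain {name!r}: overlapping ranges")
                covered |= rng

    # -- queries -----------------------------------------------------------
    def domain_names(self) -> list[str]:
        return list(self.segments)

    def residues_of(self, name: str) -> list[int]:
        out: list[int] = []
        for start, end in self.segments[name]:
            out.extend(range(start, end + 1))
        return out

    def annotate(self, number: int) -> str:
        """Domain label for an author residue number (or the unassigned label).

        With cross-domain overlaps the first-declared domain wins; call
        :meth:`validate` to list the contested residues.
        """
        for name, ranges in self.segments.items():
            if any(start <= number <= end for start, end in ranges):
                return name
        return self.unassigned_label

    def validate(self) -> dict[int, list[str]]:
        """Map of residue number -> claiming domains, for residues claimed twice."""
        claims: dict[int, list[str]] = {}
        for name in self.segments:
            for num in self.residues_of(name):
                claims.setdefault(num, []).append(name)
        return {num: names for num, names in claims.items() if len(names) > 1}

    # -- plain-text config round trip ---------------------------------------
    def to_config(self) -> str:
        lines = []
        for name, ranges in self.segments.items():
            lines.append(f"{name} = " + ",".join(f"{a}-{b}" for a, b in ranges))
        for name, residues in self.features.items():
            lines.append(f"feature {name} = " + ",".join(map(str, residues)))
        return "\n".join(lines) + "\n"

    @classmethod
    def from_config(cls, text: str) -> "DomainMap":
        segments: dict[str, list[Range]] = {}
        features: dict[str, list[int]] = {}
        for raw in text.splitlines():
            line = raw.split("#", 1)[0].strip()
            if not line:
                continue
            key, _, value = line.partition("=")
            key, value = key.strip(), value.strip()
            if key.startswith("feature "):
                features[key[len("feature "):].strip()] = [int(t) for t in value.split(",") if t.strip()]
                continue
            ranges: list[Range] = []
            for token in value.split(","):
                token = token.strip()
                if "-" in token[1:]:
                    a, b = token.rsplit("-", 1)
                    ranges.append((int(a), int(b)))
                else:
                    ranges.append((int(token), int(token)))
            segments[key] = ranges
        return cls(segments=segments, features=features)

    def save(self, path: str | Path) -> None:
        Path(path).write_text(self.to_config())

    @classmethod
    def load(cls, path: str | Path) -> "DomainMap":
        return cls.from_config(Path(path).read_text())


_PFV_FEATURES = {
    "PR_catalytic_DSG": [24, 25, 26],
    "pol_motif_YVDD": [314, 315, 316, 317],
    "pol_catalytic_Asp": [254, 316, 317],
    "primer_grip": list(range(355, 369)),
    "rnaseh_active_site": [601, 648, 671],
}


def default_pfv_map() -> DomainMap:
    """The disjoint seven-domain PFV PR-RT partition used for interface tables.

    Fingers starts at 146 (the annotated 144 would overlap PR-CTE 101–145);
    see :func:`literal_pfv_map` for the as-annotated alternative.
    """
    return DomainMap(
        segments={
            "PR": [(1, 100)],
            "PR-CTE": [(101, 145)],
            "fingers": [(146, 228), (260, 290)],
            "palm": [(229, 259), (291, 367)],
            "thumb": [(378, 449)],
            "connection": [(450, 590)],
            "RNase H": [(593, 751)],
        },
        features=dict(_PFV_FEATURES),
    )


def literal_pfv_map() -> DomainMap:
    """The as-annotated map (fingers 144–228); overlaps PR-CTE at 144–145."""
    m = default_pfv_map()
    m.segments["fingers"] = [(144, 228), (260, 290)]
    return m


@dataclass
class CoverageReport:
    """Residues expected by the map but missing from the model, per domain."""

    missing: dict[str, list[int]]
    n_unassigned_modeled: int

    def total_missing(self) -> int:
        return sum(len(v) for v in self.missing.values())


def domain_atom_groups(
    model: StructureModel,
    domain_map: DomainMap,
    chain: str | None = None,
) -> tuple[dict[str, AtomGroup], CoverageReport]:
    """Heavy, polymer, primary-conformer atoms per domain of one chain.

    Groups are disjoint (annotation resolves any cross-domain overlap);
    map residues absent from the model are counted in the coverage report,
    as are modeled residues falling in linkers.
    """
    if model.n_polymer_residues() == 0:
        raise ValueError(f"model {model.id!r} has no polymer residues")
    chain = chain or model.first_chain()
    residues = model.chains[chain]
    modeled = {r.number for r in residues}

    groups: dict[str, list[AtomRef]] = {name: [] for name in domain_map.domain_names()}
    n_unassigned = 0
    for r in residues:
        label = domain_map.annotate(r.number)
        if label == domain_map.unassigned_label:
            n_unassigned += 1
            continue
        for a in r.atoms:
            if a.is_primary and a.element != "H":
                groups[label].append((chain, r, a))

    missing = {
        name: [n for n in domain_map.residues_of(name) if n not in modeled]
        for name in domain_map.domain_names()
    }
    report = CoverageReport(missing={k: v for k, v in missing.items() if v},
                            n_unassigned_modeled=n_unassigned)
    return {name: AtomGroup(refs) for name, refs in groups.items()}, report
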