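"""Cancer-hallmark gene-set annotation.

The classifier groups differentially amplified genes by Gene Ontology (GO)
terms associated with six cancer hallmarks: apoptosis, cell adhesion, cell
cycle, cell proliferation, phosphorylation, and immune response.  The
annotation (which genes belong to which term, and which hallmark each term
represents) is a user input; this module holds the in-memory container and
the GMT / JSON readers and writers.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable

HALLMARKS: tuple[str, ...] = (
    "apoptosis",
    "cell adhesion",
    "cell cycle",
    "cell proliferation",
    "phosphorylation",
    "immune response",
)


@dataclass(frozen=True)
class GoTerm:
    """One GO term: an identifier, the hallmark it belongs to, and its genes."""

    term_id: str
    hallmark: str
    genes: tuple[str, ...]

    def __post_init__(self) -> None:
        if self.hallmark not in HALLMARKS:
            raise ValueError(
                f"unknown hallmark {self.hallmark!r} for term {self.term_id!r}; "
                f"expected one of {HALLMARKS}"
            )
        if not self.genes:
            raise ValueError(f"term {self.term_id!r} has an empty gene set")


@dataclass(frozen=True)
class HallmarkAnnotation:
    """A collection of hallmark-associated GO terms.

    A gene may belong to several terms; downstream selection deliberately
    assigns such genes to every term they annotate.
    """

    terms: tuple[GoTerm, ...] = field(default_factory=tuple)

    def __post_init__(self) -> None:
        ids = [t.term_id for t in self.terms]
        if len(set(ids)) != len(ids):
            raise ValueError("duplicate GO term identifiers in annotation")

    @property
    def term_ids(self) -> list[str]:
        return [t.term_id for t in self.terms]

    @property
    def n_terms(self) -> int:
        return len(self.terms)

    def genes(self, term_id: str) -> tuple[str, ...]:
        for t in self.terms:
            if t.term_id == term_id:
                return t.genes
        raise KeyError(term_id)

    def all_genes(self) -> list[str]:
        """Sorted union of genes over all terms."""
        out: set[str] = set()
        for t in self.terms:
            out.update(t.genes)
        return sorted(out)


def read_gmt(path: str | Path) -> HallmarkAnnotation:
    """Read a GMT file (term <TAB> hallmark-as-description <TAB> gene...)."""
    terms = []
    for line in Path(path).read_text().splitlines():
        if not line.strip():
            continue
        fields = line.rstrip("\n").split("\t")
        if len(fields) < 3:
            raise ValueError(f"malformed GMT line (need >=3 fields): {line!r}")
        terms.append(GoTerm(fields[0], fields[1], tuple(fields[2:])))
    return HallmarkAnnotation(tuple(terms))


def write_gmt(annotation: HallmarkAnnotation, path: str | Path) -> None:
    lines = [
        "\t".join([t.term_id, t.hallmark, *t.genes]) for t in annotation.terms
    ]
    Path(path).write_text("\n".join(lines) + "\n")


def read_json(path: str | Path) -> HallmarkAnnotation:
    """Read ``{term: {"hallmark": ..., "genes": [...]}}`` JSON."""
    raw = json.loads(Path(path).read_text())
    terms = [
        GoTerm(term_id, rec["hallmark"], tuple(rec["genes"]))
        for term_id, rec in raw.items()
    ]
    return HallmarkAnnotation(tuple(terms))


def write_json(annotation: HallmarkAnnotation, path: str | Path) -> None:
    raw = {
        t.term_id: {"hallmark": t.hallmark, "genes": list(t.genes)}
        for t in annotation.terms
    }
    Path(path).write_text(json.dumps(raw, indent=2) + "\n")


def read_annotation(path: str | Path) -> HallmarkAnnotation:
    """Dispatch on extension: .gmt vs .json."""
    p = Path(path)
    if p.suffix.lower() == ".gmt":
        return read_gmt(p)
    if p.suffix.lower() == ".json":
        return read_json(p)
    raise ValueError(f"unrecognised annotation format: {p.suffix!r}")


def make_annotation(
    term_to_genes: dict[str, Iterable[str]],
    hallmarks: dict[str, str] | None = None,
) -> HallmarkAnnotation:
    """Build an annotation, cycling hallmark names when not given explicitly."""
    terms = []
    for i, (term_id, genes) in enumerate(term_to_genes.items()):
        hm = (hallmarks or {}).get(term_id, HALLMARKS[i % len(HALLMARKS)])
        terms.append(GoTerm(term_id, hm, tuple(genes)))
    return HallmarkAnnotation(tuple(terms))
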