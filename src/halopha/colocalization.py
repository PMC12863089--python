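"""phaE–phaC colocalization by genomic coordinate distance.

Each phaE gene is paired with the phaC-encoding gene in the same genome
assembly that minimises ``|start(phaC) - end(phaE)|``.  The distance is
deliberately strand-agnostic — it is the literal absolute difference between
the annotated end of *phaE* and the annotated start of the candidate — so a
phaC immediately upstream on the opposite strand still scores by its start
coordinate.  A strand-aware variant (distance between the facing gene ends)
is available behind ``strand_aware=True`` but is off by default.

"Same genome" means the same assembly accession (``genome_id`` before the
first ``/``); replicon identity (the full ``genome_id``) is tracked
separately because paralogs may sit on different replicons of one assembly.
A pair is called *colocalized* when the partner exists, the distance does
not exceed ``max_distance`` and — by default — both genes share a replicon.
The raw distance is always reported so users can re-threshold.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Mapping, Sequence, TextIO

from .seqio import GeneLocus


@dataclass(frozen=True)
class ColocConfig:
    max_distance: int = 1000
    require_same_replicon: bool = True
    strand_aware: bool = False

    def __post_init__(self) -> None:
        if self.max_distance <= 0:
            raise ValueError("max_distance must be positive")


@dataclass(frozen=True)
class ColocPair:
    """A phaE locus with its nearest phaC partner (or none)."""

    phaE: GeneLocus
    phaC: GeneLocus | None
    distance: int | None
    same_replicon: bool
    colocalized: bool
    partner_class: str = ""


def _distance(phaE: GeneLocus, cand: GeneLocus, strand_aware: bool) -> int:
    if not strand_aware:
        return abs(cand.start - phaE.end)
    # facing coordinates: the candidate's transcription start is `start` on
    # the + strand and `end` on the - strand
    cand_start = cand.start if cand.strand == "+" else cand.end
    return abs(cand_start - phaE.end)


def nearest_partner(
    phaE: GeneLocus,
    candidates: Sequence[GeneLocus],
    config: ColocConfig = ColocConfig(),
) -> ColocPair:
    """Pick the candidate minimising the coordinate distance to ``phaE``.

    Ties resolve to the smaller start coordinate, then lexicographic gene id.
    Candidates on other assemblies are ignored; with no usable candidate the
    pair has an absent partner and ``colocalized`` is false.
    """
    usable = [c for c in candidates if c.assembly == phaE.assembly]
    if not usable:
        return ColocPair(phaE, None, None, False, False)
    best = min(
        usable,
        key=lambda c: (_distance(phaE, c, config.strand_aware), c.start, c.gene_id),
    )
    dist = _distance(phaE, best, config.strand_aware)
    same_rep = best.genome_id == phaE.genome_id
    coloc = dist <= config.max_distance and (same_rep or not config.require_same_replicon)
    return ColocPair(phaE, best, dist, same_rep, coloc)


def infer_pairs(
    loci: Sequence[GeneLocus],
    calls: Sequence | None = None,
    config: ColocConfig = ColocConfig(),
    partner_classes: Mapping[str, str] | None = None,
) -> list[ColocPair]:
    """One pair per phaE locus, annotated with the partner's paralog class.

    ``partner_classes`` maps phaC gene ids to class labels; alternatively
    ``calls`` (a sequence of survey ``OrganismCall`` objects) supplies the
    same mapping through each call's per-class best hits.  The result is
    sorted by (assembly, phaE gene id) and therefore independent of the
    input order of ``loci``.
    """
    classes: dict[str, str] = dict(partner_classes or {})
    if calls:
        for call in calls:
            for cls, hit in call.per_class.items():
                classes.setdefault(hit.sacc, cls)

    phaE_loci = sorted(
        (l for l in loci if l.label.lower().startswith("phae")),
        key=lambda l: (l.assembly, l.gene_id),
    )
    phaC_by_assembly: dict[str, list[GeneLocus]] = {}
    assemblies_with_loci = {l.assembly for l in loci}
    for locus in loci:
        if locus.label.lower().startswith("phac"):
            phaC_by_assembly.setdefault(locus.assembly, []).append(locus)

    pairs: list[ColocPair] = []
    for phaE in phaE_loci:
        if phaE.assembly not in assemblies_with_loci:
            raise ValueError(f"genome {phaE.assembly!r} absent from loci table")
        candidates = sorted(
            phaC_by_assembly.get(phaE.assembly, []),
            key=lambda l: (l.start, l.gene_id),
        )
        pair = nearest_partner(phaE, candidates, config)
        if pair.phaC is not None:
            cls = classes.get(pair.phaC.gene_id, "")
            pair = ColocPair(
                pair.phaE, pair.phaC, pair.distance, pair.same_replicon,
                pair.colocalized, cls,
            )
        pairs.append(pair)
    return pairs


PAIR_COLUMNS = (
    "assembly", "phaE_gene", "phaE_end", "phaC_gene", "phaC_start",
    "distance", "same_replicon", "colocalized", "partner_class",
)


def write_pairs(pairs: Iterable[ColocPair], dest: str | Path | TextIO) -> None:
    own = isinstance(dest, (str, Path))
    stream: TextIO = open(dest, "w", encoding="utf-8") if own else dest  # type: ignore[arg-type]
    try:
        stream.write("\t".join(PAIR_COLUMNS) + "\n")
        for p in pairs:
            if p.phaC is None:
                row = (p.phaE.assembly, p.phaE.gene_id, str(p.phaE.end),
                       "", "", "", str(p.same_replicon).lower(), "false", "")
            else:
                row = (
                    p.phaE.assembly, p.phaE.gene_id, str(p.phaE.end),
                    p.phaC.gene_id, str(p.phaC.start), str(p.distance),
                    str(p.same_replicon).lower(), str(p.colocalized).lower(),
                    p.partner_class,
                )
            stream.write("\t".join(row) + "\n")
    finally:
        if own:
            stream.close()
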