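"""Proteome-wide PHA-synthase paralog survey.

Mirrors a BLASTp-based comparative-genomics workflow for class III PHA
synthases in Halobacteriales: align each reference paralog (PhaC_Hme, PhaC1,
PhaC2, PhaC3, plus the PhaE subunit) against every proteome, keep the top
hits per species, drop duplicate rows, retain the best unique hit per
organism and reference class, call the best-matching class by percent
identity, flag weak calls below the 65 % identity threshold, measure query
coverage to detect terminal truncations, and tally paralog occurrence per
species.

The aligner is Smith–Waterman with affine gaps (default BLOSUM62, gap open
11, gap extend 1 — the BLASTp protein defaults) executed through biotite's
optimised dynamic-programming engine.  Bit scores use the standard gapped
Karlin–Altschul constants for BLOSUM62/11/1 (lambda = 0.267, K = 0.041);
E-values are parameterised by a database size in residues.  E-values are
reported for completeness but classification uses percent identity only.
"""

from __future__ import annotations

import json
import logging
import math
from collections import Counter
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import biotite.sequence as _seq
import biotite.sequence.align as _align

from .seqio import (
    AlignmentHit,
    GeneLocus,
    ProteinRecord,
    parse_fasta,
    write_hits,
)

logger = logging.getLogger(__name__)

#: Reference classes in their fixed tie-break order.
PHAC_CLASSES = ("PhaC_Hme", "PhaC1", "PhaC2", "PhaC3")
ALL_CLASSES = PHAC_CLASSES + ("PhaE",)

# Gapped Karlin-Altschul parameters for BLOSUM62 / open 11 / extend 1.
_KA_PARAMS = {"BLOSUM62": (0.267, 0.041)}


class ConfigError(ValueError):
    """Invalid survey configuration (e.g. unknown substitution matrix)."""


@dataclass(frozen=True)
class SurveyConfig:
    """Thresholds and scoring parameters of the survey.

    weak_threshold
        Percent identity below which a best hit is labelled *weak*
        (strict inequality: exactly 65.0 is strong). Weak calls are kept in
        the calls table but excluded from paralog tallies.
    max_targets
        Hits retained per reference x species (BLAST ``-max_target_seqs``).
    matrix / gap_open / gap_extend
        Affine-gap scoring; a gap of length k costs ``gap_open + k * gap_extend``.
    min_pident
        Alignments below this identity are not reported at all.
    database_size
        Total residues in the searched collection, used only for E-values;
        ``None`` means "length of the subject at hand".
    """

    weak_threshold: float = 65.0
    max_targets: int = 4
    matrix: str = "BLOSUM62"
    gap_open: int = 11
    gap_extend: int = 1
    min_pident: float = 25.0
    database_size: int | None = None

    def __post_init__(self) -> None:
        if not 0 < self.weak_threshold <= 100:
            raise ConfigError("weak_threshold must be in (0, 100]")
        if self.max_targets < 1:
            raise ConfigError("max_targets must be >= 1")


@dataclass(frozen=True)
class ReferenceProtein:
    """A reference query together with its paralog class label."""

    record: ProteinRecord
    class_label: str

    def __post_init__(self) -> None:
        if self.class_label not in ALL_CLASSES:
            raise ConfigError(
                f"unknown class label {self.class_label!r}; expected one of {ALL_CLASSES}"
            )


@dataclass
class OrganismCall:
    """Per-organism classification: best hit per class and the winning class."""

    organism: str
    per_class: dict[str, AlignmentHit]
    best_class: str
    best_pident: float
    strength: str  # "strong" | "weak"
    query_coverage: float

    @property
    def strong(self) -> bool:
        return self.strength == "strong"


@dataclass
class ParalogProfile:
    organism: str
    class_counts: dict[str, int]
    n_paralogs: int
    coloc_established: bool = False


@dataclass
class SurveySummary:
    total_species: int
    paralog_histogram: dict[int, int]
    most_prevalent_count: int
    class_occurrence: dict[str, int]
    n_coloc_species: int

    def to_dict(self) -> dict:
        return {
            "total_species": self.total_species,
            "paralog_histogram": {str(k): v for k, v in sorted(self.paralog_histogram.items())},
            "most_prevalent_count": self.most_prevalent_count,
            "class_occurrence": dict(self.class_occurrence),
            "n_coloc_species": self.n_coloc_species,
        }


def _substitution_matrix(name: str) -> _align.SubstitutionMatrix:
    alph = _seq.ProteinSequence.alphabet
    try:
        return _align.SubstitutionMatrix(alph, alph, name.upper())
    except Exception as exc:  # unknown matrix file
        raise ConfigError(f"unknown substitution matrix {name!r}") from exc


def bit_score(raw_score: float, matrix: str = "BLOSUM62") -> float:
    lam, k = _KA_PARAMS.get(matrix.upper(), _KA_PARAMS["BLOSUM62"])
    return float((lam * raw_score - math.log(k)) / math.log(2.0))


def local_align(
    query: ProteinRecord,
    subject: ProteinRecord,
    config: SurveyConfig = SurveyConfig(),
) -> AlignmentHit | None:
    """Best local alignment of query vs subject as a tabular hit.

    Returns ``None`` when no alignment has positive score or the identity
    falls below ``config.min_pident``.  ``pident`` is computed over all
    alignment columns including gaps, matching the BLAST tabular field.
    """
    if not query.sequence or not subject.sequence:
        raise ValueError("local_align requires non-empty sequences")
    matrix = _substitution_matrix(config.matrix)
    qseq = _seq.ProteinSequence(query.sequence)
    sseq = _seq.ProteinSequence(subject.sequence)
    # biotite charges open + (k-1)*extend for a length-k gap; BLAST charges
    # open + k*extend, hence the shifted open penalty.
    penalty = (-(config.gap_open + config.gap_extend), -config.gap_extend)
    alignments = _align.align_optimal(
        qseq, sseq, matrix, gap_penalty=penalty, local=True, max_number=1
    )
    if not alignments:
        return None
    aln = alignments[0]
    if aln.score <= 0 or len(aln.trace) == 0:
        return None

    trace = aln.trace
    identities = 0
    mismatches = 0
    gapopens = 0
    prev_gap_q = prev_gap_s = False
    for qi, si in trace:
        gap_q, gap_s = qi == -1, si == -1
        if gap_q or gap_s:
            if gap_q and not prev_gap_q:
                gapopens += 1
            if gap_s and not prev_gap_s:
                gapopens += 1
        else:
            if query.sequence[qi] == subject.sequence[si]:
                identities += 1
            else:
                mismatches += 1
        prev_gap_q, prev_gap_s = gap_q, gap_s

    length = len(trace)
    pident = 100.0 * identities / length
    if pident < config.min_pident:
        return None
    q_idx = trace[:, 0][trace[:, 0] >= 0]
    s_idx = trace[:, 1][trace[:, 1] >= 0]
    bits = bit_score(aln.score, config.matrix)
    db_size = config.database_size or len(subject.sequence)
    evalue = len(query.sequence) * db_size * 2.0 ** (-bits)
    stitle = subject.description or subject.id
    return AlignmentHit(
        qacc=query.id,
        sacc=subject.id,
        pident=pident,
        length=length,
        mismatch=mismatches,
        gapopen=gapopens,
        qstart=int(q_idx.min()) + 1,
        qend=int(q_idx.max()) + 1,
        sstart=int(s_idx.min()) + 1,
        send=int(s_idx.max()) + 1,
        evalue=evalue,
        bitscore=bits,
        stitle=stitle,
    ).canonical()


def search_homologs(
    reference: ReferenceProtein,
    proteome: Sequence[ProteinRecord],
    config: SurveyConfig = SurveyConfig(),
) -> list[AlignmentHit]:
    """Align a reference against every subject; keep the top ``max_targets``
    hits per species (subject organism), ordered by descending bit score,
    ties broken by ascending subject accession."""
    if not proteome:
        raise ValueError("proteome list is empty")
    by_species: dict[str, list[AlignmentHit]] = {}
    for subject in proteome:
        hit = local_align(reference.record, subject, config)
        if hit is not None:
            by_species.setdefault(subject.organism, []).append(hit)
    out: list[AlignmentHit] = []
    for species in sorted(by_species):
        ranked = sorted(by_species[species], key=lambda h: (-h.bitscore, h.sacc))
        out.extend(ranked[: config.max_targets])
    return out


_DEDUP_FIELDS = ("sacc", "pident", "length", "mismatch", "gapopen", "evalue", "bitscore")


def deduplicate_hits(hits: Sequence[AlignmentHit]) -> list[AlignmentHit]:
    """Collapse hits identical on the alignment-statistics key, keeping the
    first occurrence; idempotent and order preserving."""
    seen: set[tuple] = set()
    out: list[AlignmentHit] = []
    for hit in hits:
        key = tuple(getattr(hit, f) for f in _DEDUP_FIELDS)
        if key not in seen:
            seen.add(key)
            out.append(hit)
    return out


def classify_organism(
    hits_by_class: Mapping[str, Sequence[AlignmentHit]],
    organism: str,
    config: SurveyConfig = SurveyConfig(),
    reference_lengths: Mapping[str, int] | None = None,
) -> OrganismCall:
    """Retain one best unique hit per reference class and call the class with
    the highest percent identity.

    Tie-breaks (documented, not from the source workflow): within a class the
    best hit is max bitscore, then max pident, then ascending sacc; across
    classes equal pident resolves by higher bitscore, then the fixed class
    order PhaC_Hme, PhaC1, PhaC2, PhaC3.
    A call is *weak* iff best pident < ``config.weak_threshold`` (strictly).
    """
    per_class: dict[str, AlignmentHit] = {}
    for cls, hits in hits_by_class.items():
        if not hits:
            continue
        per_class[cls] = min(hits, key=lambda h: (-h.bitscore, -h.pident, h.sacc))
    if not per_class:
        raise ValueError(f"no hits for organism {organism!r}")

    order = {cls: i for i, cls in enumerate(ALL_CLASSES)}
    best_class = min(
        per_class,
        key=lambda c: (-per_class[c].pident, -per_class[c].bitscore, order.get(c, 99)),
    )
    best = per_class[best_class]
    strength = "weak" if best.pident < config.weak_threshold else "strong"
    coverage = float("nan")
    if reference_lengths and best_class in reference_lengths:
        coverage = min(100.0, 100.0 * best.length / reference_lengths[best_class])
    return OrganismCall(
        organism=organism,
        per_class=per_class,
        best_class=best_class,
        best_pident=best.pident,
        strength=strength,
        query_coverage=round(coverage, 1) if math.isfinite(coverage) else coverage,
    )


def query_coverage(hit: AlignmentHit, reference: ReferenceProtein) -> float:
    """Alignment length as a percentage of the full reference length (capped
    at 100); coverage well below 100 flags terminal truncation."""
    if hit.qacc != reference.record.id:
        raise ValueError(
            f"hit query {hit.qacc!r} does not match reference {reference.record.id!r}"
        )
    ref_len = len(reference.record.sequence)
    if ref_len == 0:
        raise ValueError("zero-length reference")
    return min(100.0, 100.0 * hit.length / ref_len)


def tally_profiles(
    calls_by_organism: Mapping[str, Mapping[str, AlignmentHit | None]] | Sequence[OrganismCall],
    coloc_pairs: Sequence | None = None,
    config: SurveyConfig = SurveyConfig(),
) -> tuple[list[ParalogProfile], SurveySummary]:
    """Count strong paralog classes per organism and summarise the survey.

    ``calls_by_organism`` may be a list of :class:`OrganismCall` (one per
    organism, carrying per-class best hits) — strong membership of *each*
    class is judged against the weak threshold per class hit, so one organism
    can contribute several classes.  Weak hits are excluded from all counts.
    """
    if isinstance(calls_by_organism, Mapping):
        raise TypeError("pass a sequence of OrganismCall")
    calls = list(calls_by_organism)
    if not calls:
        raise ValueError("no organism calls to tally")

    coloc_by_assembly: set[str] = set()
    if coloc_pairs:
        for pair in coloc_pairs:
            if getattr(pair, "colocalized", False):
                coloc_by_assembly.add(pair.phaE.assembly)

    profiles: list[ParalogProfile] = []
    class_occurrence: Counter[str] = Counter()
    histogram: Counter[int] = Counter()
    for call in sorted(calls, key=lambda c: c.organism):
        counts = {cls: 0 for cls in PHAC_CLASSES}
        for cls, hit in call.per_class.items():
            if cls in counts and hit.pident >= config.weak_threshold:
                counts[cls] = 1
        n = sum(counts.values())
        histogram[n] += 1
        class_occurrence.update(cls for cls, v in counts.items() if v)
        # organism name doubles as assembly identifier in the loci dialect
        coloc = call.organism in coloc_by_assembly
        profiles.append(ParalogProfile(call.organism, counts, n, coloc))

    max_count = max(histogram.values())
    most_prevalent = min(n for n, c in histogram.items() if c == max_count)
    summary = SurveySummary(
        total_species=len(profiles),
        paralog_histogram=dict(histogram),
        most_prevalent_count=most_prevalent,
        class_occurrence={cls: class_occurrence.get(cls, 0) for cls in PHAC_CLASSES},
        n_coloc_species=len(coloc_by_assembly),
    )
    return profiles, summary


# --- orchestration ----------------------------------------------------------

def load_references(path: str | Path) -> list[ReferenceProtein]:
    """Load a reference FASTA whose descriptions carry ``class=<label>`` tags
    (fallback: record order PhaC_Hme, PhaC1, PhaC2, PhaC3, PhaE)."""
    records = parse_fasta(path)
    refs: list[ReferenceProtein] = []
    for i, rec in enumerate(records):
        label = None
        for token in rec.description.split():
            if token.startswith("class="):
                label = token.split("=", 1)[1]
        if label is None:
            if i >= len(ALL_CLASSES):
                raise ConfigError("more references than classes and no class= tags")
            label = ALL_CLASSES[i]
        refs.append(ReferenceProtein(rec, label))
    return refs


def run_survey(
    references: Sequence[ReferenceProtein],
    proteome_paths: Sequence[str | Path],
    loci_path: str | Path | None,
    config: SurveyConfig = SurveyConfig(),
    out_dir: str | Path | None = None,
) -> dict:
    """Execute the full survey chain: search → dedup → classify → coverage →
    colocalize → tally; optionally write all intermediate tables.

    Returns a dict with keys ``hits``, ``calls``, ``pairs``, ``profiles``,
    ``summary``.
    """
    from . import colocalization
    from .seqio import read_loci

    paths = [Path(p) for p in proteome_paths]
    if not paths:
        raise ValueError("no proteomes found")
    proteome: list[ProteinRecord] = []
    for p in sorted(paths):
        records = parse_fasta(p)
        stem_org = p.stem
        for rec in records:
            if not rec.organism:
                rec = ProteinRecord(rec.id, rec.description, stem_org, rec.sequence)
            proteome.append(rec)
    logger.info("survey: %d proteins across %d proteome files", len(proteome), len(paths))

    db_size = sum(len(r.sequence) for r in proteome)
    cfg = SurveyConfig(
        weak_threshold=config.weak_threshold,
        max_targets=config.max_targets,
        matrix=config.matrix,
        gap_open=config.gap_open,
        gap_extend=config.gap_extend,
        min_pident=config.min_pident,
        database_size=config.database_size or db_size,
    )

    ref_by_class = {r.class_label: r for r in references}
    ref_lengths = {c: len(r.record.sequence) for c, r in ref_by_class.items()}

    all_hits: list[AlignmentHit] = []
    hits_by_org_class: dict[str, dict[str, list[AlignmentHit]]] = {}
    phaE_hits_by_org: dict[str, list[AlignmentHit]] = {}
    sacc_to_class: dict[str, str] = {}
    for cls in ALL_CLASSES:
        ref = ref_by_class.get(cls)
        if ref is None:
            continue
        try:
            hits = deduplicate_hits(search_homologs(ref, proteome, cfg))
        except ValueError as exc:
            raise RuntimeError(f"search stage failed for class {cls}: {exc}") from exc
        logger.info("survey: class %s -> %d hits after dedup", cls, len(hits))
        all_hits.extend(hits)
        org_of = {r.id: r.organism for r in proteome}
        for hit in hits:
            org = org_of[hit.sacc]
            if cls == "PhaE":
                phaE_hits_by_org.setdefault(org, []).append(hit)
            else:
                hits_by_org_class.setdefault(org, {}).setdefault(cls, []).append(hit)

    calls: list[OrganismCall] = []
    for org in sorted(hits_by_org_class):
        call = classify_organism(hits_by_org_class[org], org, cfg, ref_lengths)
        for cls, hit in call.per_class.items():
            if hit.pident >= cfg.weak_threshold:
                sacc_to_class[hit.sacc] = cls
        calls.append(call)

    pairs = []
    if loci_path is not None:
        loci = read_loci(loci_path)
        pairs = colocalization.infer_pairs(
            loci, partner_classes=sacc_to_class, config=colocalization.ColocConfig()
        )

    profiles, summary = tally_profiles(calls, pairs, cfg)

    if out_dir is not None:
        out = Path(out_dir)
        out.mkdir(parents=True, exist_ok=True)
        write_hits(all_hits, out / "hits.tsv")
        with open(out / "calls.tsv", "w", encoding="utf-8") as fh:
            fh.write("organism\tbest_class\tbest_pident\tstrength\tquery_coverage\tbest_sacc\n")
            for call in calls:
                fh.write(
                    f"{call.organism}\t{call.best_class}\t{call.best_pident:.3f}\t"
                    f"{call.strength}\t{call.query_coverage:.1f}\t"
                    f"{call.per_class[call.best_class].sacc}\n"
                )
        with open(out / "profiles.tsv", "w", encoding="utf-8") as fh:
            fh.write("organism\t" + "\t".join(PHAC_CLASSES) + "\tn_paralogs\tcoloc_established\n")
            for prof in profiles:
                counts = "\t".join(str(prof.class_counts[c]) for c in PHAC_CLASSES)
                fh.write(
                    f"{prof.organism}\t{counts}\t{prof.n_paralogs}\t"
                    f"{str(prof.coloc_established).lower()}\n"
                )
        if pairs:
            colocalization.write_pairs(pairs, out / "pairs.tsv")
        with open(out / "summary.json", "w", encoding="utf-8") as fh:
            json.dump(summary.to_dict(), fh, indent=2, sort_keys=True)
            fh.write("\n")

    return {
        "hits": all_hits,
        "calls": calls,
        "pairs": pairs,
        "profiles": profiles,
        "summary": summary,
    }
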