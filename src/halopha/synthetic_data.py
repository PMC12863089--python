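"""Synthetic datasets with planted ground truth for every pipeline stage.

Three generators emulate the measurement processes the analyses assume:

* **Proteome surveys** — species proteomes containing homologs mutated to a
  controlled percent identity against each reference paralog class
  (conservative, substitution-matrix-biased mutations so local alignability
  is retained), optionally truncated from both termini, padded with
  composition-shuffled decoy proteins that align to no reference; a gene
  locus table plants a phaE→phaC coordinate distance.
* **RT-qPCR** — Ct tables following
  ``Ct = baseline − log_E(template) + N(0, sd)`` with per-gene
  amplification efficiencies, planted fold changes between conditions,
  stable reference genes, a biological × technical replicate structure and
  10-fold dilution series consistent with each planted efficiency.
* **¹H-NMR methine peak lists** — a 3HB and a 3HV methine peak whose
  integrals are proportional to the planted monomer mole fractions, plus
  optional spurious peaks and multiplicative integral noise.

Every generator call is driven by a single integer seed (no global random
state); identical spec + seed gives byte-identical output files.  Each
generator returns (and optionally writes) a ground-truth sidecar recording
the planted parameters so downstream recovery can be checked exactly.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .seqio import AMINO_ACIDS, ProteinRecord, write_fasta, write_loci, GeneLocus
from .paralog_survey import (
    ALL_CLASSES,
    PHAC_CLASSES,
    ReferenceProtein,
    SurveyConfig,
    local_align,
)

logger = logging.getLogger(__name__)

_MIN_TARGET_IDENTITY = 25.0
_IDENTITY_TOLERANCE = 3.0
#: Decoys must stay below this identity against every reference.
DECOY_MAX_PIDENT = 40.0

# BLOSUM62 amino-acid background frequencies (Robinson & Robinson order of
# AMINO_ACIDS), used for decoy composition.
_BACKGROUND = {
    "A": 0.078, "C": 0.019, "D": 0.054, "E": 0.063, "F": 0.039,
    "G": 0.073, "H": 0.022, "I": 0.052, "K": 0.057, "L": 0.090,
    "M": 0.022, "N": 0.045, "P": 0.052, "Q": 0.043, "R": 0.051,
    "S": 0.071, "T": 0.058, "V": 0.064, "W": 0.013, "Y": 0.032,
}


def _blosum62_rows() -> dict[str, tuple[tuple[str, ...], np.ndarray]]:
    """Per-residue conservative replacement candidates and weights."""
    import biotite.sequence as _seq
    import biotite.sequence.align as _align

    matrix = _align.SubstitutionMatrix.std_protein_matrix()
    alph = matrix.get_alphabet1()
    rows: dict[str, tuple[tuple[str, ...], np.ndarray]] = {}
    for a in AMINO_ACIDS:
        scores = {
            b: matrix.get_score(a, b)
            for b in AMINO_ACIDS
            if b != a
        }
        best = max(scores.values())
        threshold = 0 if best >= 0 else best
        cands = tuple(sorted(b for b, s in scores.items() if s >= threshold))
        weights = np.array([np.exp(scores[b]) for b in cands])
        rows[a] = (cands, weights / weights.sum())
    return rows


_SUBSTITUTION_ROWS: dict[str, tuple[tuple[str, ...], np.ndarray]] | None = None


def _substitution_rows() -> dict[str, tuple[tuple[str, ...], np.ndarray]]:
    global _SUBSTITUTION_ROWS
    if _SUBSTITUTION_ROWS is None:
        _SUBSTITUTION_ROWS = _blosum62_rows()
    return _SUBSTITUTION_ROWS


def _measure_identity(reference: ProteinRecord, mutant: ProteinRecord,
                      config: SurveyConfig) -> float:
    hit = local_align(reference, mutant, config)
    return hit.pident if hit is not None else 0.0


def mutate_to_identity(
    reference: ProteinRecord,
    target_identity: float,
    seed: int,
    config: SurveyConfig = SurveyConfig(),
) -> ProteinRecord:
    """Mutate a reference to a planted percent identity (±3 points).

    Substitutions are drawn at positions chosen without replacement and
    replace each residue with a conservatively scoring partner (BLOSUM62
    score ≥ 0, weighted by exp(score)), so the mutant remains locally
    alignable to its reference and the identity realised by
    :func:`~halopha.paralog_survey.local_align` tracks the planted value.
    Targets below 25 % are refused: that far out conservative substitution
    can no longer guarantee a faithful full-length alignment.
    """
    if not 0 < target_identity <= 100:
        raise ValueError("target identity must be in (0, 100]")
    if target_identity < _MIN_TARGET_IDENTITY:
        raise ValueError(
            f"target identity {target_identity} < {_MIN_TARGET_IDENTITY}%: "
            "alignability cannot be guaranteed at this divergence"
        )
    length = len(reference.sequence)
    if target_identity == 100:
        return ProteinRecord(reference.id + "_hom", reference.description,
                             reference.organism, reference.sequence)

    rng = np.random.default_rng(seed)
    rows = _substitution_rows()
    order = rng.permutation(length)  # substitution order, fixed by seed
    n_sub = int(round(length * (1.0 - target_identity / 100.0)))
    n_sub = min(n_sub, length)

    def apply(n: int) -> ProteinRecord:
        mutated = list(reference.sequence)
        for pos in order[:n]:
            a = reference.sequence[pos]
            if a not in rows:  # X stays X
                continue
            cands, weights = rows[a]
            mutated[pos] = cands[rng.choice(len(cands), p=weights)]
        return ProteinRecord(
            reference.id + "_hom", reference.description, reference.organism,
            "".join(mutated),
        )

    # The realised identity is re-measured with the survey aligner and the
    # substitution count adjusted until it lands inside the tolerance band.
    mutant = apply(n_sub)
    for _ in range(30):
        measured = _measure_identity(reference, mutant, config)
        if abs(measured - target_identity) <= _IDENTITY_TOLERANCE:
            break
        step = max(1, int(round(abs(measured - target_identity) / 100.0 * length)))
        if measured > target_identity:
            n_sub = min(length, n_sub + step)
        else:
            n_sub = max(0, n_sub - step)
        mutant = apply(n_sub)
    else:
        raise RuntimeError(
            f"could not reach target identity {target_identity}% for {reference.id}"
        )
    return mutant


def truncate_termini(record: ProteinRecord, fraction: float) -> ProteinRecord:
    """Keep the central ``round(fraction * length)`` residues, removing the
    remainder from both termini proportionally."""
    if not 0 < fraction <= 1:
        raise ValueError("truncation fraction must be in (0, 1]")
    length = len(record.sequence)
    keep = max(1, int(round(fraction * length)))
    start = (length - keep) // 2
    return ProteinRecord(record.id, record.description, record.organism,
                         record.sequence[start : start + keep])


def random_decoy(rng: np.random.Generator, length: int) -> str:
    letters = np.array(list(_BACKGROUND))
    probs = np.array(list(_BACKGROUND.values()))
    probs = probs / probs.sum()
    return "".join(rng.choice(letters, size=length, p=probs))


@dataclass(frozen=True)
class PlantedHit:
    """One homolog to plant: reference class, target identity, truncation."""

    class_label: str
    identity: float
    truncation: float = 1.0

    def __post_init__(self) -> None:
        if self.class_label not in ALL_CLASSES:
            raise ValueError(f"unknown class {self.class_label!r}")
        if not 0 < self.identity <= 100:
            raise ValueError("identity must be in (0, 100]")
        if not 0 < self.truncation <= 1:
            raise ValueError("truncation fraction must be in (0, 1]")


@dataclass(frozen=True)
class SurveyTruth:
    """Planted composition of one synthetic species."""

    species: str
    planted_hits: tuple[PlantedHit, ...]
    phaE_present: bool = False
    phaE_identity: float = 90.0
    phaE_to_phaC_distance: int | None = None  # signed bp; partner = first hit
    n_decoys: int = 20


def generate_survey_dataset(
    truths: Sequence[SurveyTruth],
    references: Sequence[ReferenceProtein],
    out_dir: str | Path,
    seed: int,
    config: SurveyConfig = SurveyConfig(),
) -> dict:
    """Write per-species proteome FASTAs, a loci TSV and a truth sidecar.

    Each species proteome holds one mutated (and possibly truncated)
    homolog per planted hit, a phaE homolog when requested, and
    ``n_decoys`` shuffled-composition decoys verified to align to no
    reference at ≥ 40 % identity.  The loci table places the phaE gene and
    its intended phaC partner at the planted signed distance
    (``|start(phaC) − end(phaE)| = |distance|``); remaining planted genes
    are placed far apart.
    """
    species_names = [t.species for t in truths]
    if len(set(species_names)) != len(species_names):
        raise ValueError("duplicate species names in truths")
    ref_by_class = {r.class_label: r for r in references}
    missing = set(PHAC_CLASSES) - set(ref_by_class)
    if missing:
        raise ValueError(f"references missing classes {sorted(missing)}")

    out = Path(out_dir)
    proteome_dir = out / "proteomes"
    proteome_dir.mkdir(parents=True, exist_ok=True)

    loci: list[GeneLocus] = []
    truth_rows: list[dict] = []
    proteome_paths: list[Path] = []

    for sp_index, truth in enumerate(truths):
        rng = np.random.default_rng([seed, sp_index])
        records: list[ProteinRecord] = []
        genome = f"{truth.species}/chr1"
        gene_positions: dict[str, tuple[int, int]] = {}

        phaE_end = 10_000
        if truth.phaE_present:
            if "PhaE" not in ref_by_class:
                raise ValueError("phaE planted but no PhaE reference given")
            phaE_ref = ref_by_class["PhaE"].record
            phaE_seed = int(rng.integers(2**31))
            phaE_rec = mutate_to_identity(phaE_ref, truth.phaE_identity,
                                          phaE_seed, config)
            phaE_id = f"{truth.species}_phaE"
            records.append(ProteinRecord(
                phaE_id, f"PHA synthase subunit PhaE [{truth.species}]",
                truth.species, phaE_rec.sequence,
            ))
            glen = 3 * len(phaE_rec.sequence) + 3
            gene_positions[phaE_id] = (phaE_end - glen + 1, phaE_end)
            loci.append(GeneLocus(genome, phaE_id, phaE_end - glen + 1,
                                  phaE_end, "+", "phaE"))

        far = 100_000
        for j, planted in enumerate(truth.planted_hits):
            ref = ref_by_class[planted.class_label].record
            sub_seed = int(rng.integers(2**31))
            homolog = mutate_to_identity(ref, planted.identity, sub_seed, config)
            if planted.truncation < 1:
                homolog = truncate_termini(homolog, planted.truncation)
            acc = f"{truth.species}_p{j:02d}"
            records.append(ProteinRecord(
                acc,
                f"{planted.class_label}-like PHA synthase [{truth.species}]",
                truth.species,
                homolog.sequence,
            ))
            glen = 3 * len(homolog.sequence) + 3
            if j == 0 and truth.phaE_present and truth.phaE_to_phaC_distance is not None:
                start = phaE_end + truth.phaE_to_phaC_distance
                if start < 1:
                    raise ValueError("planted distance places gene before position 1")
            else:
                start = far
                far += 100_000
            loci.append(GeneLocus(genome, acc, start, start + glen - 1, "+",
                                  "phaC-like"))
            realized = _measure_identity(ref, homolog, config)
            truth_rows.append({
                "species": truth.species,
                "gene_id": acc,
                "class": planted.class_label,
                "target_identity": planted.identity,
                "realized_identity": round(realized, 3),
                "truncation": planted.truncation,
                "expected_strength": "strong" if planted.identity >= config.weak_threshold else "weak",
                "phaE_present": truth.phaE_present,
                "phaE_to_phaC_distance": (
                    truth.phaE_to_phaC_distance
                    if (j == 0 and truth.phaE_present and truth.phaE_to_phaC_distance is not None)
                    else ""
                ),
            })

        refs_for_check = [r.record for r in references]
        n_done = 0
        attempts = 0
        while n_done < truth.n_decoys:
            attempts += 1
            if attempts > 50 * truth.n_decoys:
                raise RuntimeError("decoy generation failed to satisfy the identity bound")
            length = int(rng.integers(150, 450))
            seq = random_decoy(rng, length)
            decoy = ProteinRecord(f"{truth.species}_d{n_done:03d}", "", truth.species, seq)
            if any(
                (hit := local_align(ref, decoy, config)) is not None
                and hit.pident >= DECOY_MAX_PIDENT
                for ref in refs_for_check
            ):
                continue
            records.append(ProteinRecord(
                decoy.id, f"hypothetical protein [{truth.species}]",
                truth.species, seq,
            ))
            n_done += 1

        path = proteome_dir / f"{truth.species}.fasta"
        write_fasta(records, path)
        proteome_paths.append(path)
        logger.info("synthetic proteome %s: %d proteins (%d decoys)",
                    truth.species, len(records), truth.n_decoys)

    loci_path = out / "loci.tsv"
    write_loci(loci, loci_path)
    truth_df = pd.DataFrame(truth_rows)
    truth_path = out / "truth.tsv"
    truth_df.to_csv(truth_path, sep="\t", index=False)
    return {
        "proteome_paths": proteome_paths,
        "loci_path": loci_path,
        "truth_path": truth_path,
        "truth": truth_df,
    }


# --- qPCR -------------------------------------------------------------------


@dataclass(frozen=True)
class QpcrSimSpec:
    """Planted parameters of a synthetic RT-qPCR experiment.

    ``fold_changes`` maps ``(gene, sample_condition, control_condition)`` to
    the planted expression ratio; genes without an entry (the reference
    genes) keep a constant template level across conditions.  Template
    levels start at 1.0 in the first condition and propagate through the
    planted folds.
    """

    genes: tuple[str, ...] = ("phaC_Hme", "phaC1", "phaC2", "phaC3")
    reference_genes: tuple[str, ...] = ("tbp", "ffs")
    conditions: tuple[str, ...] = ("mid_exponential", "stationary")
    efficiencies: Mapping[str, float] = field(default_factory=dict)
    fold_changes: Mapping[tuple[str, str, str], float] = field(default_factory=dict)
    baseline_ct: float = 22.0
    n_bio: int = 3
    n_tech: int = 2
    ct_noise_sd: float = 0.0
    dilution_points: int = 5
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_bio < 1 or self.n_tech < 1:
            raise ValueError("replicate counts must be >= 1")
        if self.ct_noise_sd < 0:
            raise ValueError("ct_noise_sd must be >= 0")
        if self.dilution_points < 3:
            raise ValueError("dilution series needs >= 3 points")
        for gene, e in self.efficiencies.items():
            if not 1.0 < e <= 2.2:
                raise ValueError(f"efficiency of {gene!r} must be in (1, 2.2]")
        for key, fold in self.fold_changes.items():
            if fold <= 0:
                raise ValueError(f"fold change for {key} must be positive")

    def efficiency(self, gene: str) -> float:
        return float(self.efficiencies.get(gene, 2.0))

    @property
    def all_genes(self) -> tuple[str, ...]:
        return self.genes + self.reference_genes


def _template_levels(spec: QpcrSimSpec) -> dict[str, dict[str, float]]:
    levels = {g: {spec.conditions[0]: 1.0} for g in spec.all_genes}
    pending = dict(spec.fold_changes)
    for _ in range(len(pending) + 1):
        resolved = []
        for (gene, sample, control), fold in pending.items():
            if control in levels[gene]:
                levels[gene][sample] = levels[gene][control] * fold
                resolved.append((gene, sample, control))
        for key in resolved:
            del pending[key]
        if not pending:
            break
    if pending:
        raise ValueError(f"fold changes with unresolvable control conditions: {sorted(pending)}")
    for gene in spec.all_genes:
        for cond in spec.conditions:
            levels[gene].setdefault(cond, 1.0)
    return levels


def generate_qpcr_dataset(
    spec: QpcrSimSpec,
    out_dir: str | Path | None = None,
) -> tuple[pd.DataFrame, pd.DataFrame, pd.DataFrame]:
    """Simulate Ct measurements and dilution series for a planted design.

    Returns ``(ct_table, dilution_table, truth_table)``; with ``out_dir``
    also writes ``ct.csv``, ``dilutions.csv`` and ``truth.tsv``.

    The measurement model is ``Ct = baseline − log_E(template) + N(0, sd)``
    per (gene, condition, biological, technical) observation; the dilution
    series obeys ``Ct = baseline + slope · log10(Q)`` with
    ``slope = −ln 10 / ln E`` so the fitted curve recovers the planted
    efficiency exactly when noise-free.
    """
    rng = np.random.default_rng(spec.seed)
    levels = _template_levels(spec)

    ct_rows = []
    for gene in spec.all_genes:
        e = spec.efficiency(gene)
        for cond in spec.conditions:
            expected = spec.baseline_ct - np.log(levels[gene][cond]) / np.log(e)
            for bio in range(1, spec.n_bio + 1):
                for tech in range(1, spec.n_tech + 1):
                    noise = rng.normal(0.0, spec.ct_noise_sd) if spec.ct_noise_sd else 0.0
                    ct_rows.append({
                        "gene": gene, "condition": cond, "bio_rep": bio,
                        "tech_rep": tech, "ct": round(expected + noise, 6),
                    })
    ct_df = pd.DataFrame(ct_rows)

    dil_rows = []
    for gene in spec.all_genes:
        e = spec.efficiency(gene)
        slope = -np.log(10.0) / np.log(e)
        for d in range(spec.dilution_points):
            log10_q = float(-d)
            noise = rng.normal(0.0, spec.ct_noise_sd) if spec.ct_noise_sd else 0.0
            dil_rows.append({
                "gene": gene, "log10_quantity": log10_q,
                "ct": round(spec.baseline_ct + slope * log10_q + noise, 6),
            })
    dil_df = pd.DataFrame(dil_rows)

    truth_rows = [
        {"gene": g, "sample": s, "control": c, "planted_fold": f,
         "efficiency": spec.efficiency(g)}
        for (g, s, c), f in sorted(spec.fold_changes.items())
    ]
    for ref in spec.reference_genes:
        truth_rows.append({"gene": ref, "sample": "", "control": "",
                           "planted_fold": 1.0, "efficiency": spec.efficiency(ref)})
    truth_df = pd.DataFrame(truth_rows)

    if out_dir is not None:
        out = Path(out_dir)
        out.mkdir(parents=True, exist_ok=True)
        ct_df.to_csv(out / "ct.csv", index=False)
        dil_df.to_csv(out / "dilutions.csv", index=False)
        truth_df.to_csv(out / "truth.tsv", sep="\t", index=False)
    return ct_df, dil_df, truth_df


# --- NMR --------------------------------------------------------------------


@dataclass(frozen=True)
class NmrSimSpec:
    """Planted composition of a synthetic PHBV methine peak list."""

    hv_mole_fraction: float
    total_methine_integral: float = 100.0
    shift_3hb: float = 5.25
    shift_3hv: float = 5.15
    integral_noise_sd: float = 0.0
    extra_peaks: tuple[tuple[float, float], ...] = ()
    seed: int = 0

    def __post_init__(self) -> None:
        if not 0 <= self.hv_mole_fraction <= 1:
            raise ValueError("hv_mole_fraction must be in [0, 1]")
        if self.shift_3hb == self.shift_3hv:
            raise ValueError("3HB and 3HV shifts must be distinct")
        if self.integral_noise_sd < 0:
            raise ValueError("integral_noise_sd must be >= 0")


def generate_nmr_peaklist(
    spec: NmrSimSpec,
    out_path: str | Path | None = None,
) -> tuple[pd.DataFrame, dict]:
    """Emit a methine-region peak list at a planted 3HV mole fraction.

    The 3HB and 3HV methine integrals are proportional to the monomer mole
    fractions (one methine proton per monomer), each multiplied by
    ``(1 + N(0, noise_sd))`` and clipped at zero; extra peaks pass through
    unchanged.  Returns ``(peak_table, truth)``; with ``out_path`` also
    writes the CSV (truth sidecar next to it as ``<stem>.truth.json``).
    """
    rng = np.random.default_rng(spec.seed)

    def noisy(value: float) -> float:
        if spec.integral_noise_sd:
            value *= 1.0 + rng.normal(0.0, spec.integral_noise_sd)
        return max(0.0, value)

    i_b = noisy((1.0 - spec.hv_mole_fraction) * spec.total_methine_integral)
    i_v = noisy(spec.hv_mole_fraction * spec.total_methine_integral)
    rows = [
        {"shift_ppm": spec.shift_3hb, "integral": round(i_b, 6)},
        {"shift_ppm": spec.shift_3hv, "integral": round(i_v, 6)},
    ]
    rows.extend({"shift_ppm": s, "integral": i} for s, i in spec.extra_peaks)
    peaks = pd.DataFrame(rows)
    truth = {
        "hv_mole_fraction": spec.hv_mole_fraction,
        "hv_mol_percent": 100.0 * spec.hv_mole_fraction,
    }
    if out_path is not None:
        out = Path(out_path)
        out.parent.mkdir(parents=True, exist_ok=True)
        peaks.to_csv(out, index=False)
        import json

        with open(out.with_suffix(".truth.json"), "w", encoding="utf-8") as fh:
            json.dump(truth, fh, indent=2)
            fh.write("\n")
    return peaks, truth


def synthetic_references(
    seed: int = 0,
    length: int = 480,
    phaE_length: int = 180,
) -> list[ReferenceProtein]:
    """A synthetic reference set: one random protein per paralog class.

    Stands in for a real reference collection when none is supplied;
    independent random draws make cross-class identities background-level
    (~5-10 %), giving clean class separation for planted-truth experiments.
    """
    refs: list[ReferenceProtein] = []
    for i, cls in enumerate(ALL_CLASSES):
        rng = np.random.default_rng([seed, 1000 + i])
        n = phaE_length if cls == "PhaE" else length
        seq = random_decoy(rng, n)
        rec = ProteinRecord(
            f"SYNREF_{cls}", f"synthetic {cls} reference class={cls}", "", seq
        )
        refs.append(ReferenceProtein(rec, cls))
    return refs
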