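"""Seeded synthetic-data generators with known ground truth.

Every pipeline stage has a generator that emulates its real input:

* :func:`gen_panel` — labeled protein panels with planted class-segregating
  substitutions (e.g. a D/H site mimicking Asp332His), confounded columns
  whose residues mix across classes (the Ala/Pro pattern at position 140),
  background mutations, and matched coding sequences via a fixed
  reverse-translation codon table;
* :func:`gen_trajectory` — toy trajectories with residue pairs placed in
  contact in a prescribed fraction of frames and filter residues given
  isotropic Gaussian positional jitter;
* :func:`gen_ct_table` — qPCR Ct tables with prescribed fold changes and
  Gaussian noise, reference-gene wells included;
* :func:`gen_photometer` — linear flame-photometer responses with noise.

Generators are pure functions of their spec (the seed lives in the spec):
the same spec reproduces byte-identical outputs.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Literal, Mapping, Sequence

import numpy as np
import pandas as pd

from .expression_pfaffl import CtTable
from .sequence_io import SeqRecord
from .substitution_scan import AlignmentMatrix, LabeledSequencePanel
from .trajectory_metrics import AtomRecord, Trajectory

__all__ = [
    "PanelSpec",
    "TrajectorySpec",
    "ContactPairSpec",
    "CtSpec",
    "PhotometerSpec",
    "gen_panel",
    "gen_trajectory",
    "gen_ct_table",
    "gen_photometer",
    "RICE_CODON_TABLE",
]

AMINO_ACIDS = "ACDEFGHIKLMNPQRSTVWY"

# Fixed reverse-translation table (common rice codon per residue) so the
# nucleotide-level ground truth of generated panels is stable.  The choices
# at D/H and V/L match the codon pairs observed at the HKT1;5 SNP sites
# (GAC/CAC at CDS 994-996, GTC/CTC at 1183-1185).
RICE_CODON_TABLE = {
    "A": "GCC", "C": "TGC", "D": "GAC", "E": "GAG", "F": "TTC",
    "G": "GGC", "H": "CAC", "I": "ATC", "K": "AAG", "L": "CTC",
    "M": "ATG", "N": "AAC", "P": "CCG", "Q": "CAG", "R": "AGG",
    "S": "AGC", "T": "ACC", "V": "GTC", "W": "TGG", "Y": "TAC",
}
STOP_CODON = "TAA"


def reverse_translate(protein: str) -> str:
    """Fixed-codon back-translation, terminal stop appended."""
    return "".join(RICE_CODON_TABLE[aa] for aa in protein) + STOP_CODON


# ---------------------------------------------------------------------------
# Labeled sequence panels


@dataclass(frozen=True)
class PanelSpec:
    """Recipe for a labeled panel with planted segregation signal.

    ``planted_sites`` are (position, tolerant residue, sensitive residue)
    triples; moderately tolerant sequences carry the *sensitive* residue
    there, so folding them into the tolerant class breaks strictness — the
    behaviour the label-policy switch exists to exercise.  ``confounded_sites``
    cycle a residue pool (default A/P) within every class so neither class
    owns a residue.  ``background_rate`` is a per-position substitution
    probability applied outside planted/confounded columns.
    """

    n_tolerant: int = 4
    n_sensitive: int = 4
    n_moderate: int = 0
    length: int = 120
    planted_sites: tuple[tuple[int, str, str], ...] = ()
    confounded_sites: tuple[int, ...] = ()
    confound_pool: tuple[str, str] = ("A", "P")
    background_rate: float = 0.0
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_tolerant < 1 or self.n_sensitive < 1:
            raise ValueError("need at least one tolerant and one sensitive sequence")
        planted = {p for p, _, _ in self.planted_sites}
        if len(planted) != len(self.planted_sites):
            raise ValueError("duplicate planted positions")
        if planted & set(self.confounded_sites):
            raise ValueError("planted and confounded positions must be disjoint")
        for pos in planted | set(self.confounded_sites):
            if not 1 <= pos <= self.length:
                raise ValueError(f"site position {pos} outside sequence length {self.length}")
        for pos, t, s in self.planted_sites:
            if t == s:
                raise ValueError(f"planted site {pos}: tolerant and sensitive residues must differ")
            if t not in AMINO_ACIDS or s not in AMINO_ACIDS:
                raise ValueError(f"planted site {pos}: residues must be standard amino acids")
        if not 0.0 <= self.background_rate <= 0.3:
            raise ValueError(
                "background_rate outside [0, 0.3]: higher rates cannot preserve "
                "the planted ground truth reliably"
            )


def gen_panel(
    spec: PanelSpec,
) -> tuple[LabeledSequencePanel, AlignmentMatrix, dict[str, str], dict]:
    """Generate a labeled panel, its (gap-free) alignment, matched CDS, and
    the ground truth of planted/confounded sites."""
    rng = np.random.default_rng(spec.seed)
    base = "".join(rng.choice(list(AMINO_ACIDS), size=spec.length))
    planted = {pos: (t, s) for pos, t, s in spec.planted_sites}

    records: list[SeqRecord] = []
    labels: dict[str, str] = {}
    class_plan = (
        [("tol", "tolerant")] * spec.n_tolerant
        + [("sen", "sensitive")] * spec.n_sensitive
        + [("mod", "moderately_tolerant")] * spec.n_moderate
    )
    counters: dict[str, int] = {}
    for prefix, label in class_plan:
        counters[prefix] = counters.get(prefix, 0) + 1
        rid = f"{prefix}{counters[prefix]}"
        rank = counters[prefix] - 1
        seq = list(base)
        for pos, (t_res, s_res) in planted.items():
            seq[pos - 1] = t_res if label == "tolerant" else s_res
        for pos in spec.confounded_sites:
            seq[pos - 1] = spec.confound_pool[rank % len(spec.confound_pool)]
        if spec.background_rate > 0:
            protected = set(planted) | set(spec.confounded_sites)
            hits = np.nonzero(rng.random(spec.length) < spec.background_rate)[0]
            for k in hits:
                if (k + 1) in protected:
                    continue
                choices = [a for a in AMINO_ACIDS if a != seq[k]]
                seq[k] = choices[int(rng.integers(len(choices)))]
        records.append(SeqRecord(id=rid, residues="".join(seq), alphabet="protein"))
        labels[rid] = label

    panel = LabeledSequencePanel(records=tuple(records), labels=labels)
    aln = AlignmentMatrix([r.id for r in records], [r.residues for r in records])
    cds_by_id = {r.id: reverse_translate(r.residues) for r in records}
    truth = {
        "planted_sites": {pos: {"tolerant": t, "sensitive": s} for pos, (t, s) in planted.items()},
        "confounded_sites": list(spec.confounded_sites),
        "seed": spec.seed,
    }
    return panel, aln, cds_by_id, truth


HKT_VARIANT_SITES = {140: ("P", "A"), 184: ("H", "R"), 332: ("D", "H"), 395: ("V", "L")}


def hkt_standin_pair(length: int = 554, seed: int = 20260101) -> tuple[SeqRecord, SeqRecord]:
    """Synthetic stand-in for the tolerant/sensitive rice HKT1;5 pair.

    Two deterministic protein sequences of HKT1;5-like length, identical
    except at the four documented variant positions (140, 184, 332, 395),
    where the first record carries the tolerant-type residues (P, H, D, V)
    and the second the sensitive-type residues (A, R, H, L).  These are
    synthetic sequences — not the database accessions — built so pairwise
    analyses exercise the documented difference pattern without network
    access.
    """
    rng = np.random.default_rng(seed)
    base = list(rng.choice(list(AMINO_ACIDS), size=length))
    tol = base.copy()
    sen = base.copy()
    for pos, (t, s) in HKT_VARIANT_SITES.items():
        tol[pos - 1] = t
        sen[pos - 1] = s
    return (
        SeqRecord(id="tolerant_standin", residues="".join(tol), alphabet="protein",
                  description="tolerant_standin synthetic HKT1;5-like (Nona Bokra-type variants)"),
        SeqRecord(id="sensitive_standin", residues="".join(sen), alphabet="protein",
                  description="sensitive_standin synthetic HKT1;5-like (Nipponbare-type variants)"),
    )


# ---------------------------------------------------------------------------
# Trajectories


@dataclass(frozen=True)
class ContactPairSpec:
    """One residue pair with a target contact occupancy.

    ``deterministic`` placement puts the pair in contact in exactly
    ``round(occupancy * n_frames)`` frames (the leading ones); ``random``
    draws each frame's contact state as an independent Bernoulli trial.
    """

    res_a: int
    res_b: int
    occupancy: float
    mode: Literal["deterministic", "random"] = "deterministic"

    def __post_init__(self) -> None:
        if not 0.0 <= self.occupancy <= 1.0:
            raise ValueError("occupancy must lie in [0, 1]")
        if self.res_a == self.res_b:
            raise ValueError("a contact pair needs two distinct residues")


@dataclass(frozen=True)
class TrajectorySpec:
    """Recipe for a toy trajectory with known contact and jitter truth."""

    n_frames: int = 100
    contact_pairs: tuple[ContactPairSpec, ...] = ()
    filter_residues: tuple[int, ...] = (76, 264, 391, 495)
    filter_sigma: float = 0.5  # Å, isotropic per-axis Gaussian jitter
    contact_distance: float = 3.0  # Å, in-contact placement
    apart_distance: float = 10.0  # Å, out-of-contact placement
    cutoff: float = 4.2
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_frames < 1:
            raise ValueError("need at least one frame")
        if self.filter_sigma < 0:
            raise ValueError("filter_sigma must be non-negative")
        if not self.contact_distance < self.cutoff < self.apart_distance:
            raise ValueError(
                "geometrically infeasible: need contact_distance < cutoff < apart_distance"
            )
        seen: set[int] = set()
        for p in self.contact_pairs:
            if p.res_a in seen or p.res_b in seen:
                raise ValueError("each residue may participate in at most one contact pair")
            seen.update((p.res_a, p.res_b))
        if seen & set(self.filter_residues):
            raise ValueError("contact-pair residues and filter residues must be disjoint")


def gen_trajectory(spec: TrajectorySpec) -> tuple[Trajectory, dict]:
    """Build the trajectory and return it with realised ground truth.

    Anchor residues sit on a widely spaced grid (one heavy side-chain atom
    each) so no accidental contacts arise; partner residues toggle between
    ``contact_distance`` and ``apart_distance`` from their anchor; filter
    residues jitter isotropically about their own grid home.
    """
    rng = np.random.default_rng(spec.seed)
    residues: list[int] = []
    for p in spec.contact_pairs:
        residues.extend((p.res_a, p.res_b))
    residues.extend(spec.filter_residues)

    spacing = 4.0 * spec.apart_distance  # keeps unrelated residues far apart
    homes: dict[int, np.ndarray] = {}
    slot = 0
    for p in spec.contact_pairs:
        homes[p.res_a] = np.array([slot * spacing, 0.0, 0.0])
        homes[p.res_b] = homes[p.res_a] + np.array([spec.apart_distance, 0.0, 0.0])
        slot += 1
    for res in spec.filter_residues:
        homes[res] = np.array([slot * spacing, spacing, 0.0])
        slot += 1

    atoms = [
        AtomRecord(residue_index=res, residue_name="ALA", atom_name="CB", element="C")
        for res in residues
    ]
    atom_of = {res: k for k, res in enumerate(residues)}

    coords = np.tile(
        np.stack([homes[res] for res in residues]), (spec.n_frames, 1, 1)
    )

    truth_pairs = {}
    for p in spec.contact_pairs:
        if p.mode == "deterministic":
            k = int(round(p.occupancy * spec.n_frames))
            contact_frames = np.zeros(spec.n_frames, dtype=bool)
            contact_frames[:k] = True
        else:
            contact_frames = rng.random(spec.n_frames) < p.occupancy
        offs = np.where(contact_frames, spec.contact_distance, spec.apart_distance)
        coords[:, atom_of[p.res_b], 0] = homes[p.res_a][0] + offs
        truth_pairs[(p.res_a, p.res_b)] = {
            "target_occupancy": p.occupancy,
            "realized_occupancy": float(contact_frames.mean()),
            "mode": p.mode,
        }

    for res in spec.filter_residues:
        if spec.filter_sigma > 0:
            coords[:, atom_of[res], :] += rng.normal(
                0.0, spec.filter_sigma, size=(spec.n_frames, 3)
            )

    traj = Trajectory(atoms, list(coords))
    truth = {
        "contact_pairs": truth_pairs,
        "filter_sigma": spec.filter_sigma,
        "filter_residues": list(spec.filter_residues),
        "seed": spec.seed,
    }
    return traj, truth


# ---------------------------------------------------------------------------
# qPCR Ct tables


@dataclass(frozen=True)
class CtSpec:
    """Recipe for a Ct table with prescribed relative-expression truth.

    Target-gene Ct for a group with true fold change F is
    ``baseline_target − log2(F) + ε``; the reference gene sits at
    ``baseline_reference + ε`` (ε ~ N(0, noise_sd) per well).  Defaults
    mirror a three-genotype salt-stress design with six biological and
    three technical replicates.
    """

    genotypes: tuple[str, ...] = ("IR29", "Pokkali", "Pcoarctata")
    conditions: tuple[object, ...] = (0, 100, 200)
    control_condition: object = 0
    fold_changes: Mapping[str, Mapping[object, float]] = field(
        default_factory=lambda: {
            "IR29": {0: 1.0, 100: 2.4, 200: 1.0},
            "Pokkali": {0: 1.0, 100: 2.4, 200: 1.2},
            "Pcoarctata": {0: 1.0, 100: 3.0, 200: 7.5},
        }
    )
    tissue: str = "root"
    baseline_target: float = 25.0
    baseline_reference: float = 20.0
    noise_sd: float = 0.1
    n_bio: int = 6
    n_tech: int = 3
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_bio < 1 or self.n_tech < 1:
            raise ValueError("replicate counts must be >= 1")
        for g in self.genotypes:
            for c in self.conditions:
                f = self.fold_changes.get(g, {}).get(c)
                if f is None:
                    raise ValueError(f"no fold change specified for ({g}, {c})")
                if f <= 0:
                    raise ValueError(f"fold change for ({g}, {c}) must be positive")


def gen_ct_table(spec: CtSpec) -> tuple[CtTable, pd.DataFrame]:
    """Generate the Ct table and a truth table of intended ratios."""
    rng = np.random.default_rng(spec.seed)
    rows = []
    truth_rows = []
    for g in spec.genotypes:
        for c in spec.conditions:
            fold = spec.fold_changes[g][c]
            truth_rows.append({"genotype": g, "condition": c, "true_ratio": fold})
            for b in range(1, spec.n_bio + 1):
                sample_id = f"{g}_{c}_b{b}"
                for gene, base in (
                    ("target", spec.baseline_target - np.log2(fold)),
                    ("reference", spec.baseline_reference),
                ):
                    for t in range(1, spec.n_tech + 1):
                        rows.append(
                            {
                                "sample_id": sample_id,
                                "genotype": g,
                                "tissue": spec.tissue,
                                "condition": c,
                                "gene": gene,
                                "bio_rep": b,
                                "tech_rep": t,
                                "ct": base + rng.normal(0.0, spec.noise_sd),
                            }
                        )
    return CtTable(pd.DataFrame(rows)), pd.DataFrame(truth_rows)


# ---------------------------------------------------------------------------
# Flame-photometer readings


@dataclass(frozen=True)
class PhotometerSpec:
    """Linear photometer response with Gaussian reading noise."""

    ion: str = "Na"
    slope: float = 1.5
    intercept: float = 0.2
    standards_ppm: tuple[float, ...] = (10.0, 8.0, 6.0, 4.0, 2.0, 1.0, 0.5)
    sample_ppm: tuple[float, ...] = (3.0, 5.0, 7.0)
    noise_sd: float = 0.05
    seed: int = 0

    def __post_init__(self) -> None:
        if self.slope <= 0:
            raise ValueError("slope must be positive")
        if self.noise_sd < 0:
            raise ValueError("noise_sd must be non-negative")


def gen_photometer(spec: PhotometerSpec) -> tuple[pd.DataFrame, pd.DataFrame, dict]:
    """Standards and sample readings plus ground truth (slope, ppm)."""
    rng = np.random.default_rng(spec.seed)
    std = pd.DataFrame(
        {
            "ppm": spec.standards_ppm,
            "reading": [
                spec.slope * c + spec.intercept + rng.normal(0.0, spec.noise_sd)
                for c in spec.standards_ppm
            ],
        }
    )
    samples = pd.DataFrame(
        {
            "sample_id": [f"s{i + 1}" for i in range(len(spec.sample_ppm))],
            "reading": [
                spec.slope * c + spec.intercept + rng.normal(0.0, spec.noise_sd)
                for c in spec.sample_ppm
            ],
        }
    )
    truth = {
        "slope": spec.slope,
        "intercept": spec.intercept,
        "sample_ppm": list(spec.sample_ppm),
        "seed": spec.seed,
    }
    return std, samples, truth
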