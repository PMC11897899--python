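"""Seeded simulation of two-group repertoire studies and clinical cohorts.

The repertoire generator draws, per sample:

* V and J usage from a Dirichlet centred on a locus-wide prior
  (``concentration`` controls sample-to-sample noise), with planted
  per-group usage multipliers applied before renormalization;
* CDR3 lengths from a discretized Gaussian (mode 15 aa for TRB, 20 aa for
  IGH, sd 1.2, truncated to 8..28) so the modal spectratype window spans
  14-16 aa (TRB) / 19-21 aa (IGH);
* CDR3 strings with a fixed N-terminal cysteine, a C-terminal
  phenylalanine (TRB) or tryptophan/phenylalanine mix (IGH), and interior
  residues i.i.d. from a stated 20-letter multinomial — positional
  structure beyond the anchors is deliberately not modelled;
* clone sizes from a Zipf law (default exponent 1.5, jittered per sample)
  followed by multinomial read sampling at the configured depth; a planted
  expansion multiplies the weight of the top clones in the target group,
  concentrating read mass and lowering evenness there.

Every sample draws from its own RNG stream derived from ``(seed, sample
index)`` via :class:`numpy.random.SeedSequence`, so per-sample output is
independent of generation order and identical config+seed reproduces
byte-identical files.

The cohort generator emits a two-arm clinical cohort (default 69 TP / 19
FP) with per-arm best-response allocations, exponential progression-free
and overall survival with response-group-specific medians (rate =
ln 2 / median), uniform-thinning censoring, and per-term adverse events.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Mapping, Sequence

import numpy as np

from . import genes
from .cohort import ARMS, RESPONSES, PatientRecord
from .errors import ConfigError
from .io import (
    AA_ALPHABET,
    GROUPS,
    ClonotypeRecord,
    RepertoireSample,
    StudyDesign,
    merge_duplicates,
)

# Interior-residue multinomial: mildly enriched for the small/flexible and
# charged residues that dominate junctional regions, depleted for C/W/M.
_INTERIOR_WEIGHTS = {
    "A": 6.0, "C": 1.0, "D": 5.0, "E": 5.0, "F": 3.5,
    "G": 9.0, "H": 2.0, "I": 3.5, "K": 4.0, "L": 7.0,
    "M": 1.5, "N": 4.0, "P": 4.0, "Q": 4.5, "R": 6.0,
    "S": 9.0, "T": 6.0, "V": 4.5, "W": 1.0, "Y": 5.0,
}

#: Default lead genes for the usage priors: the most frequently rearranged
#: V segments (TRBV20-1, TRBV12-3) and J segments (TRBJ2-7, TRBJ2-1) for
#: TRB; IGHV3-21 and IGHJ4/IGHJ6 for IGH.
_PRIOR_WEIGHTS = {
    "TRB": {
        "V": {"TRBV20-1": 3.2, "TRBV12-3": 2.8, "TRBV28": 1.7, "TRBV6-5": 1.7,
              "TRBV3-1": 1.6, "TRBV5-1": 1.6,
              # low-frequency segments carrying the default planted shifts:
              # a 3x shift on these stays well below the lead genes
              "TRBV29-1": 0.6, "TRBV4-1": 0.6},
        "J": {"TRBJ2-7": 3.0, "TRBJ2-1": 2.6, "TRBJ1-2": 1.8, "TRBJ1-6": 1.8,
              "TRBJ1-1": 1.5, "TRBJ1-3": 0.6},
    },
    "IGH": {
        "V": {"IGHV3-21": 3.0, "IGHV1-69": 2.2, "IGHV1-18": 2.0, "IGHV3-23": 1.9,
              "IGHV1-45": 0.6, "IGHV3-20": 0.6, "IGHV3-48": 0.6,
              "IGHV3-49": 0.6, "IGHV4-4": 0.6, "IGHV5-51": 0.6},
        "J": {"IGHJ4": 3.0, "IGHJ6": 2.5, "IGHJ3": 1.5, "IGHJ5": 1.5},
    },
}

_LENGTH_MODE = {"TRB": 15.0, "IGH": 20.0}
_LENGTH_SD = 1.2
_LENGTH_RANGE = (8, 28)


def _default_prior(locus: str, segment: str) -> dict[str, float]:
    names = genes.v_genes(locus) if segment == "V" else genes.j_genes(locus)
    lead = _PRIOR_WEIGHTS[locus][segment]
    w = np.array([lead.get(g, 1.0) for g in names], dtype=float)
    w /= w.sum()
    return dict(zip(names, w))


@dataclass(frozen=True)
class PlantedUsageShift:
    """Multiply one gene's usage prior in one group before renormalizing."""

    gene: str
    multiplier: float
    group: str  # "non_ORR" | "ORR"


@dataclass(frozen=True)
class PlantedExpansion:
    """Multiply the clone-size weight of the top clones in one group."""

    factor: float
    group: str
    n_clones: int = 10


@dataclass(frozen=True)
class RepertoireSimConfig:
    locus: str = "TRB"
    n_samples_per_group: int = 15
    clonotypes_per_sample: int = 1000
    total_reads_per_sample: int = 30000
    v_usage_prior: Mapping[str, float] | None = None
    j_usage_prior: Mapping[str, float] | None = None
    concentration: float = 250.0
    cdr3_length_mean: float | None = None  # defaults per locus: 15 / 20
    cdr3_length_sd: float = _LENGTH_SD
    zipf_exponent: float = 1.5
    zipf_sd: float = 0.1
    planted_usage: tuple[PlantedUsageShift, ...] = ()
    planted_expansion: PlantedExpansion | None = None

    def __post_init__(self) -> None:
        if self.locus not in ("TRB", "IGH"):
            raise ConfigError(f"unknown locus {self.locus!r}")
        if self.n_samples_per_group < 1 or self.clonotypes_per_sample < 1:
            raise ConfigError("sample and clonotype counts must be positive")
        for prior in (self.v_usage_prior, self.j_usage_prior):
            if prior is not None:
                vals = np.array(list(prior.values()), dtype=float)
                if np.any(vals <= 0) or abs(vals.sum() - 1.0) > 1e-6:
                    raise ConfigError("usage priors must be positive and sum to 1")
        for plant in self.planted_usage:
            if plant.multiplier <= 0:
                raise ConfigError("usage multipliers must be > 0")
            if plant.group not in GROUPS:
                raise ConfigError(f"unknown plant group {plant.group!r}")
        if self.planted_expansion and self.planted_expansion.factor <= 0:
            raise ConfigError("expansion factor must be > 0")

    def prior(self, segment: str) -> dict[str, float]:
        configured = self.v_usage_prior if segment == "V" else self.j_usage_prior
        if configured is not None:
            return dict(configured)
        return _default_prior(self.locus, segment)

    def length_pmf(self) -> tuple[np.ndarray, np.ndarray]:
        mean = self.cdr3_length_mean or _LENGTH_MODE[self.locus]
        lo, hi = _LENGTH_RANGE
        lengths = np.arange(lo, hi + 1)
        dens = np.exp(-0.5 * ((lengths - mean) / self.cdr3_length_sd) ** 2)
        return lengths, dens / dens.sum()

    def manifest(self) -> dict:
        return {
            "locus": self.locus,
            "n_samples_per_group": self.n_samples_per_group,
            "clonotypes_per_sample": self.clonotypes_per_sample,
            "total_reads_per_sample": self.total_reads_per_sample,
            "concentration": self.concentration,
            "cdr3_length_mean": self.cdr3_length_mean or _LENGTH_MODE[self.locus],
            "cdr3_length_sd": self.cdr3_length_sd,
            "zipf_exponent": self.zipf_exponent,
            "planted_usage": [
                {"gene": p.gene, "multiplier": p.multiplier, "group": p.group}
                for p in self.planted_usage
            ],
            "planted_expansion": (
                {
                    "factor": self.planted_expansion.factor,
                    "group": self.planted_expansion.group,
                    "n_clones": self.planted_expansion.n_clones,
                }
                if self.planted_expansion
                else None
            ),
        }


def default_trb_config(**overrides) -> RepertoireSimConfig:
    """TRB study defaults: the group effects the analysis is built to find.

    Plants a 3x usage shift on TRBV29-1, TRBV4-1 and TRBJ1-3 in the ORR
    group, plus a clonal expansion there (lower evenness / inverse Simpson).
    """
    cfg = RepertoireSimConfig(
        locus="TRB",
        planted_usage=(
            PlantedUsageShift("TRBV29-1", 3.0, "ORR"),
            PlantedUsageShift("TRBV4-1", 3.0, "ORR"),
            PlantedUsageShift("TRBJ1-3", 3.0, "ORR"),
        ),
        planted_expansion=PlantedExpansion(factor=3.0, group="ORR", n_clones=10),
    )
    return replace(cfg, **overrides) if overrides else cfg


def default_igh_config(**overrides) -> RepertoireSimConfig:
    """IGH study defaults: six planted differential V genes, no J shift and
    no expansion (group diversity comparable by construction)."""
    planted = tuple(
        PlantedUsageShift(g, 3.0, "ORR")
        for g in ("IGHV1-45", "IGHV3-20", "IGHV3-48",
                  "IGHV3-49", "IGHV4-4", "IGHV5-51")
    )
    cfg = RepertoireSimConfig(locus="IGH", planted_usage=planted)
    return replace(cfg, **overrides) if overrides else cfg


# ---------------------------------------------------------------------------
# Repertoire generation


def _sample_rng(seed: int, sample_index: int) -> np.random.Generator:
    return np.random.default_rng(np.random.SeedSequence([int(seed), sample_index]))


def _draw_usage(
    rng: np.random.Generator,
    prior: dict[str, float],
    plants: Sequence[PlantedUsageShift],
    group: str,
    concentration: float,
) -> tuple[list[str], np.ndarray]:
    names = list(prior)
    base = np.array([prior[g] for g in names], dtype=float)
    probs = rng.dirichlet(base * concentration)
    for plant in plants:
        if plant.group == group and plant.gene in prior:
            probs[names.index(plant.gene)] *= plant.multiplier
    return names, probs / probs.sum()


def _draw_cdr3s(
    rng: np.random.Generator, lengths: np.ndarray, locus: str
) -> list[str]:
    """Vectorized CDR3 strings: fixed anchors, i.i.d. interior residues."""
    aa_codes = np.frombuffer(AA_ALPHABET.encode(), dtype=np.uint8)
    interior_p = np.array([_INTERIOR_WEIGHTS[a] for a in AA_ALPHABET])
    interior_p /= interior_p.sum()

    out = np.empty(len(lengths), dtype=object)
    for L in np.unique(lengths):
        idx = np.flatnonzero(lengths == L)
        k = len(idx)
        arr = np.empty((k, L), dtype=np.uint8)
        arr[:, 0] = ord("C")
        if L > 2:
            arr[:, 1:-1] = aa_codes[
                rng.choice(len(aa_codes), size=(k, L - 2), p=interior_p)
            ]
        if locus == "TRB":
            arr[:, -1] = ord("F")
        else:
            arr[:, -1] = np.where(rng.random(k) < 0.7, ord("W"), ord("F"))
        out[idx] = arr.view(f"S{L}").ravel().astype(str)
    return list(out)


def simulate_repertoire(
    config: RepertoireSimConfig,
    group: str,
    seed: int,
    sample_index: int = 0,
    sample_id: str | None = None,
) -> RepertoireSample:
    """Draw one repertoire sample for the given group."""
    if group not in GROUPS:
        raise ConfigError(f"unknown group {group!r}")
    rng = _sample_rng(seed, sample_index)
    K = config.clonotypes_per_sample

    v_names, v_probs = _draw_usage(
        rng, config.prior("V"), config.planted_usage, group, config.concentration
    )
    j_names, j_probs = _draw_usage(
        rng, config.prior("J"), config.planted_usage, group, config.concentration
    )
    v_idx = rng.choice(len(v_names), size=K, p=v_probs)
    j_idx = rng.choice(len(j_names), size=K, p=j_probs)

    lengths_support, length_p = config.length_pmf()
    lengths = rng.choice(lengths_support, size=K, p=length_p)
    cdr3s = _draw_cdr3s(rng, lengths, config.locus)

    # clone-size weights: Zipf law with per-sample exponent jitter
    z = max(0.5, rng.normal(config.zipf_exponent, config.zipf_sd))
    weights = np.arange(1, K + 1, dtype=float) ** (-z)
    plant = config.planted_expansion
    if plant is not None and plant.group == group:
        weights[: plant.n_clones] *= plant.factor
    counts = rng.multinomial(config.total_reads_per_sample, weights / weights.sum())

    sid = sample_id or f"{config.locus}_{group}_{sample_index:02d}"
    keep = np.flatnonzero(counts)
    records = [
        ClonotypeRecord(
            sample_id=sid,
            locus=config.locus,
            v_call=v_names[v_idx[i]],
            j_call=j_names[j_idx[i]],
            cdr3_aa=cdr3s[i],
            count=int(counts[i]),
        )
        for i in keep
    ]
    return RepertoireSample(
        sample_id=sid,
        locus=config.locus,
        records=merge_duplicates(records),
        group=group,
    )


def simulate_study(
    config: RepertoireSimConfig, seed: int
) -> tuple[list[RepertoireSample], StudyDesign, dict]:
    """Draw a full two-group study plus its ground-truth manifest."""
    samples: list[RepertoireSample] = []
    mapping: dict[str, str] = {}
    index = 0
    for group in GROUPS:
        for _ in range(config.n_samples_per_group):
            s = simulate_repertoire(config, group, seed, sample_index=index)
            samples.append(s)
            mapping[s.sample_id] = group
            index += 1
    design = StudyDesign(groups=mapping, locus=config.locus)
    manifest = {"seed": int(seed), **config.manifest()}
    return samples, design, manifest


# ---------------------------------------------------------------------------
# Cohort generation

#: per-arm best-response allocations (CR, PR, SD, PD)
_DEFAULT_RESPONSE_COUNTS = {
    "TP": {"CR": 0, "PR": 43, "SD": 20, "PD": 6},
    "FP": {"CR": 0, "PR": 11, "SD": 4, "PD": 4},
}

#: patient-level adverse-event occurrence probabilities (term -> n/88)
_DEFAULT_AE_PROBS = {
    "RCCEP": 14 / 88, "Fever": 8 / 88, "Neutropenia": 6 / 88,
    "Thrombocytopenia": 4 / 88, "Leukopenia": 4 / 88, "Anemia": 4 / 88,
    "Pneumonia": 4 / 88, "Nausea/vomiting": 4 / 88, "Rashes": 3 / 88,
    "Diarrhea": 1 / 88, "Hyperthyroidism": 1 / 88,
    "Bipedal numbness": 1 / 88, "Esophageal fistula": 1 / 88,
}

#: conditional grade distribution per AE occurrence (grades 1..5)
_DEFAULT_GRADE_PROBS = (0.45, 0.35, 0.15, 0.04, 0.01)


@dataclass(frozen=True)
class CohortSimConfig:
    n_patients: int = 88
    arm_sizes: Mapping[str, int] = field(
        default_factory=lambda: {"TP": 69, "FP": 19}
    )
    response_counts: Mapping[str, Mapping[str, int]] = field(
        default_factory=lambda: {
            arm: dict(v) for arm, v in _DEFAULT_RESPONSE_COUNTS.items()
        }
    )
    exact_counts: bool = True  # allocate responses exactly; False -> multinomial
    pfs_median_responder: float = 18.37
    pfs_median_nonresponder: float = 8.07
    os_median_responder: float = 28.27
    os_median_nonresponder: float = 22.33
    censor_rate: float = 0.0
    ae_probs: Mapping[str, float] = field(
        default_factory=lambda: dict(_DEFAULT_AE_PROBS)
    )
    grade_probs: tuple[float, ...] = _DEFAULT_GRADE_PROBS

    def __post_init__(self) -> None:
        if sum(self.arm_sizes.values()) != self.n_patients:
            raise ConfigError("arm sizes must sum to n_patients")
        if set(self.arm_sizes) != set(ARMS):
            raise ConfigError(f"arms must be exactly {ARMS}")
        for m in (self.pfs_median_responder, self.pfs_median_nonresponder,
                  self.os_median_responder, self.os_median_nonresponder):
            if m <= 0:
                raise ConfigError("survival medians must be > 0")
        if not 0.0 <= self.censor_rate < 1.0:
            raise ConfigError("censor_rate must lie in [0, 1)")
        if abs(sum(self.grade_probs) - 1.0) > 1e-9 or len(self.grade_probs) != 5:
            raise ConfigError("grade_probs must be 5 probabilities summing to 1")
        for p in self.ae_probs.values():
            if not 0.0 <= p <= 1.0:
                raise ConfigError("AE probabilities must lie in [0, 1]")


def _arm_responses(
    rng: np.random.Generator, cfg: CohortSimConfig, arm: str
) -> list[str]:
    n = cfg.arm_sizes[arm]
    counts = {r: int(cfg.response_counts[arm].get(r, 0)) for r in RESPONSES}
    total = sum(counts.values())
    if cfg.exact_counts and total == n:
        responses = [r for r in RESPONSES for _ in range(counts[r])]
    else:
        probs = np.array([counts[r] / total for r in RESPONSES])
        draw = rng.multinomial(n, probs)
        responses = [r for r, k in zip(RESPONSES, draw) for _ in range(k)]
    rng.shuffle(responses)
    return responses


def simulate_cohort(config: CohortSimConfig, seed: int) -> list[PatientRecord]:
    """Draw a two-arm cohort with responses, survival times and AEs."""
    rng = np.random.default_rng(np.random.SeedSequence([int(seed), 991]))
    ln2 = np.log(2.0)
    patients = []
    pid = 0
    terms = list(config.ae_probs)
    for arm in ARMS:
        for response in _arm_responses(rng, config, arm):
            pid += 1
            responder = response in ("CR", "PR")
            pfs_med = (
                config.pfs_median_responder if responder
                else config.pfs_median_nonresponder
            )
            os_med = (
                config.os_median_responder if responder
                else config.os_median_nonresponder
            )
            # PFS = min(time-to-progression, death): with exponential
            # components the marginals stay exactly exponential at the
            # configured medians and PFS <= OS holds by construction.
            os_ = float(rng.exponential(os_med / ln2))
            ttp_rate = ln2 / pfs_med - ln2 / os_med
            if ttp_rate > 0:
                pfs = min(float(rng.exponential(1.0 / ttp_rate)), os_)
            else:  # degenerate config (PFS median >= OS median): uncoupled
                pfs = min(float(rng.exponential(pfs_med / ln2)), os_)
            pfs_event = os_event = True
            if config.censor_rate > 0.0:
                if rng.random() < config.censor_rate:
                    pfs *= rng.random()
                    pfs_event = False
                if rng.random() < config.censor_rate:
                    os_ *= rng.random()
                    os_event = False
            aes = [
                (term, int(1 + rng.choice(5, p=config.grade_probs)))
                for term in terms
                if rng.random() < config.ae_probs[term]
            ]
            patients.append(
                PatientRecord(
                    patient_id=f"P{pid:03d}",
                    regimen=arm,
                    best_response=response,
                    pfs_months=pfs,
                    pfs_event=pfs_event,
                    os_months=os_,
                    os_event=os_event,
                    ae_list=aes,
                )
            )
    return patients
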