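"""Synthetic mtDNA cohorts with known ground truth.

Generates participant genomes (the rCRS with substitutions and indels
planted at configurable carrier frequencies, including IUPAC-ambiguous
calls), sociodemographic/clinical metadata drawn from the marginal
distributions of a Chinese ART-naive HIV cohort (74% male, median age
37, 95% Han ethnicity, 69%/29% heterosexual/homosexual transmission,
77% on the zidovudine-based first-line regimen, median pre-ART CD4
219 cells/ul), and CD4 outcomes from a linear model with planted variant
effects, covariate effects and heavy-tailed (Laplace) noise — the
error structure that motivates median regression downstream.

Everything derives from one master seed; regenerating with the same
seed is byte-identical.  The emitted ground-truth ledger (carrier
matrix plus the exact variant objects written into each genome) lets
every downstream stage be audited exactly.

Variants are sampled independently across participants and positions —
no linkage or haplogroup structure — because the association scan
treats substitutions marginally.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from .calling import Variant, left_align_deletion, left_align_insertion
from .reference import MitoReference

#: IUPAC code for a two-base mixture.
_MIX = {
    frozenset("AG"): "R", frozenset("CT"): "Y", frozenset("CG"): "S",
    frozenset("AT"): "W", frozenset("GT"): "K", frozenset("AC"): "M",
}

_TRANSITION_PARTNER = {"A": "G", "G": "A", "C": "T", "T": "C"}

AGE_GROUP_RANGES = {
    "17-29": (17, 29), "30-44": (30, 44), "45-59": (45, 59), ">=60": (60, 79),
}


@dataclass(frozen=True)
class PlantedVariant:
    """A substitution to plant: rCRS position, ref>alt, carrier frequency,
    and its additive effect (cells/ul) on the post-ART CD4 outcome."""

    position: int
    ref: str
    alt: str
    frequency: float
    effect: float = 0.0

    @property
    def m_notation(self) -> str:
        return f"m.{self.position}{self.ref}>{self.alt}"


@dataclass(frozen=True)
class PlantedIndel:
    position: int          # deletion: first deleted base; insertion: anchor
    kind: str              # "deletion" | "insertion"
    bases: str             # deleted reference bases / inserted bases
    frequency: float

    @property
    def m_notation(self) -> str:
        if self.kind == "deletion":
            if len(self.bases) == 1:
                return f"m.{self.position}del"
            return f"m.{self.position}_{self.position + len(self.bases) - 1}del"
        return f"m.{self.position}_{self.position + 1}ins{self.bases}"


@dataclass(frozen=True)
class CovariateMarginals:
    """Marginal distributions of the cohort metadata."""

    male: float = 0.7418
    age_group_probs: tuple[float, ...] = (0.3014, 0.4054, 0.1881, 0.1051)
    han: float = 0.9451
    transmission_probs: tuple[float, ...] = (0.6904, 0.2862, 0.0234)
    regimen_probs: tuple[float, ...] = (0.7707, 0.1630, 0.0663)
    duration_ge3: float = 0.5967
    cd4_pre_log_median: float = math.log(219.0)
    cd4_pre_log_sigma: float = 0.5


@dataclass(frozen=True)
class OutcomeModel:
    """cd4_post = cd4_pre + intercept + covariate effects + variant effects
    + noise, truncated at 0.  Defaults centre the pre-to-post change near
    the observed median of 70 cells/ul with Laplace noise whose scale
    reproduces an interquartile range of roughly 130 cells/ul."""

    intercept: float = 70.0
    age_per_year: float = -0.8      # centred at age 37
    female: float = 5.0
    minority: float = 0.0
    homosexual: float = 5.0
    other_transmission: float = 0.0
    regimen_d4t: float = -10.0
    regimen_other: float = -5.0
    duration_ge3: float = 15.0
    noise: str = "laplace"          # "laplace" | "normal"
    noise_scale: float = 90.0


@dataclass(frozen=True)
class SimulationConfig:
    n_participants: int = 724
    variants: tuple[PlantedVariant, ...] = ()
    indels: tuple[PlantedIndel, ...] = ()
    ambiguity_rate: float = 0.04
    covariates: CovariateMarginals = field(default_factory=CovariateMarginals)
    outcome: OutcomeModel = field(default_factory=OutcomeModel)
    seed: int = 0
    on_conflict: str = "error"      # "error" | "resample"

    def __post_init__(self) -> None:
        for v in self.variants:
            if not 0.0 <= v.frequency < 1.0:
                raise ValueError(f"{v.m_notation}: frequency must be in [0, 1)")
        for d in self.indels:
            if not 0.0 <= d.frequency < 1.0:
                raise ValueError(f"{d.m_notation}: frequency must be in [0, 1)")


@dataclass
class SyntheticCohort:
    """A simulated cohort plus its exact ground truth."""

    sequences: dict[str, str] | None
    metadata: pd.DataFrame
    carriers: pd.DataFrame            # participants x planted events (bool)
    emitted: dict[str, list[Variant]]  # exactly what each genome contains
    config: SimulationConfig

    @property
    def sample_ids(self) -> list[str]:
        return list(self.metadata["id"])

    def genotype_matrix(self) -> pd.DataFrame:
        """0/1 carrier matrix over planted substitution columns."""
        cols = [v.m_notation for v in self.config.variants]
        return self.carriers[cols].astype(int)

    def write(self, outdir: str | Path) -> None:
        outdir = Path(outdir)
        outdir.mkdir(parents=True, exist_ok=True)
        if self.sequences is not None:
            with open(outdir / "cohort.fasta", "w") as fh:
                for sid, seq in self.sequences.items():
                    fh.write(f">{sid}\n")
                    for i in range(0, len(seq), 70):
                        fh.write(seq[i : i + 70] + "\n")
        self.metadata.to_csv(outdir / "metadata.tsv", sep="\t", index=False)
        self.carriers.astype(int).to_csv(outdir / "carriers.tsv", sep="\t")
        with open(outdir / "config.yaml", "w") as fh:
            yaml.safe_dump(_config_dict(self.config), fh, sort_keys=False)


def _config_dict(config: SimulationConfig) -> dict:
    return {
        "n_participants": config.n_participants,
        "seed": config.seed,
        "ambiguity_rate": config.ambiguity_rate,
        "on_conflict": config.on_conflict,
        "variants": [vars(v).copy() for v in config.variants],
        "indels": [vars(d).copy() for d in config.indels],
        "covariates": vars(config.covariates).copy(),
        "outcome": vars(config.outcome).copy(),
    }


def age_group_of(age: int | float) -> str:
    if age < 30:
        return "17-29"
    if age < 45:
        return "30-44"
    if age < 60:
        return "45-59"
    return ">=60"


def _validate_against_reference(config: SimulationConfig, ref: MitoReference) -> None:
    positions: dict[int, str] = {}
    for v in config.variants:
        if ref.base(v.position) != v.ref:
            raise ValueError(
                f"{v.m_notation}: reference base at {v.position} is "
                f"{ref.base(v.position)!r}"
            )
        if v.position in positions:
            if config.on_conflict == "error":
                raise ValueError(
                    f"two planted variants at position {v.position}; "
                    "set on_conflict='resample' to allow"
                )
        positions[v.position] = v.alt
    for d in config.indels:
        if d.kind == "deletion":
            expected = ref.sequence[d.position - 1 : d.position - 1 + len(d.bases)]
            if expected != d.bases:
                raise ValueError(f"{d.m_notation}: reference bases are {expected!r}")


def simulate_cohort(
    config: SimulationConfig,
    ref: MitoReference,
    build_sequences: bool = True,
) -> SyntheticCohort:
    """Draw a full synthetic cohort from one master seed.

    Carrier status is Bernoulli per participant per planted event.  With
    ``build_sequences=False`` only metadata, outcomes and the carrier
    ledger are generated (sufficient for association-scan studies and
    far faster than writing 16.5-kb genomes).
    """
    _validate_against_reference(config, ref)
    rng = np.random.default_rng(np.random.SeedSequence(config.seed))
    n = config.n_participants
    cov = config.covariates
    ids = [f"S{i:04d}" for i in range(1, n + 1)]

    male = rng.random(n) < cov.male
    group_idx = rng.choice(4, size=n, p=np.asarray(cov.age_group_probs) /
                           np.sum(cov.age_group_probs))
    groups = list(AGE_GROUP_RANGES)
    ages = np.array(
        [
            rng.integers(
                AGE_GROUP_RANGES[groups[g]][0], AGE_GROUP_RANGES[groups[g]][1] + 1
            )
            for g in group_idx
        ]
    )
    han = rng.random(n) < cov.han
    trans_idx = rng.choice(
        3, size=n, p=np.asarray(cov.transmission_probs) /
        np.sum(cov.transmission_probs)
    )
    regimen_idx = rng.choice(
        3, size=n, p=np.asarray(cov.regimen_probs) / np.sum(cov.regimen_probs)
    )
    duration_ge3 = rng.random(n) < cov.duration_ge3
    cd4_pre = np.round(
        rng.lognormal(cov.cd4_pre_log_median, cov.cd4_pre_log_sigma, size=n)
    )

    events: list[PlantedVariant | PlantedIndel] = list(config.variants) + list(
        config.indels
    )
    carrier = np.zeros((n, len(events)), dtype=bool)
    for j, ev in enumerate(events):
        carrier[:, j] = rng.random(n) < ev.frequency
    # resolve participants carrying two substitutions at one position
    pos_groups: dict[int, list[int]] = {}
    for j, v in enumerate(config.variants):
        pos_groups.setdefault(v.position, []).append(j)
    for pos, js in pos_groups.items():
        if len(js) < 2:
            continue
        conflicted = carrier[:, js].sum(axis=1) > 1
        for i in np.where(conflicted)[0]:
            keep = rng.choice(js)
            for j in js:
                carrier[i, j] = j == keep
    ambiguous = rng.random((n, len(config.variants))) < config.ambiguity_rate

    om = config.outcome
    effects = np.array(
        [v.effect for v in config.variants] + [0.0] * len(config.indels)
    )
    mean_change = (
        om.intercept
        + om.age_per_year * (ages - 37.0)
        + om.female * (~male)
        + om.minority * (~han)
        + om.homosexual * (trans_idx == 1)
        + om.other_transmission * (trans_idx == 2)
        + om.regimen_d4t * (regimen_idx == 1)
        + om.regimen_other * (regimen_idx == 2)
        + om.duration_ge3 * duration_ge3
        + carrier @ effects
    )
    if om.noise == "laplace":
        noise = rng.laplace(0.0, om.noise_scale, size=n)
    elif om.noise == "normal":
        noise = rng.normal(0.0, om.noise_scale, size=n)
    else:
        raise ValueError(f"unknown noise family {om.noise!r}")
    cd4_post = np.maximum(np.round(cd4_pre + mean_change + noise), 0.0)

    metadata = pd.DataFrame(
        {
            "id": ids,
            "gender": np.where(male, "male", "female"),
            "age": ages,
            "age_group": [age_group_of(a) for a in ages],
            "ethnicity": np.where(han, "Han", "minority"),
            "transmission": np.array(["heterosexual", "homosexual", "other"])[
                trans_idx
            ],
            "cd4_pre": cd4_pre,
            "cd4_post": cd4_post,
            "immune_level": np.where(cd4_pre < 200, "severe", "mild"),
            "regimen": np.array(
                ["EFV/NVP+3TC+AZT", "EFV/NVP+3TC+d4T", "others"]
            )[regimen_idx],
            "duration_class": np.where(duration_ge3, ">=3", "<3"),
        }
    )
    carriers = pd.DataFrame(
        carrier, index=ids, columns=[ev.m_notation for ev in events]
    )
    carriers.index.name = "id"

    emitted: dict[str, list[Variant]] = {}
    sequences: dict[str, str] | None = {} if build_sequences else None
    for i, sid in enumerate(ids):
        evs: list[Variant] = []
        for j, v in enumerate(config.variants):
            if not carrier[i, j]:
                continue
            if ambiguous[i, j] and frozenset((v.ref, v.alt)) in _MIX:
                alt = _MIX[frozenset((v.ref, v.alt))]
            else:
                alt = v.alt
            evs.append(Variant(v.position, v.ref, alt, "substitution"))
        for k, d in enumerate(config.indels):
            if not carrier[i, len(config.variants) + k]:
                continue
            if d.kind == "deletion":
                pos = left_align_deletion(ref.sequence, d.position, len(d.bases))
                bases = ref.sequence[pos - 1 : pos - 1 + len(d.bases)]
                evs.append(Variant(pos, bases, "", "deletion"))
            else:
                anchor, bases = left_align_insertion(
                    ref.sequence, d.position, d.bases
                )
                evs.append(Variant(anchor, "", bases, "insertion"))
        evs.sort()
        emitted[sid] = evs
        if build_sequences:
            sequences[sid] = apply_variants(ref.sequence, evs)

    return SyntheticCohort(
        sequences=sequences,
        metadata=metadata,
        carriers=carriers,
        emitted=emitted,
        config=config,
    )


def apply_variants(sequence: str, variants: list[Variant]) -> str:
    """Apply non-overlapping variants to a sequence (highest position first)."""
    seq = list(sequence)
    for v in sorted(variants, reverse=True):
        if v.kind == "substitution":
            seq[v.position - 1] = v.alt
        elif v.kind == "deletion":
            del seq[v.position - 1 : v.position - 1 + len(v.ref)]
        else:
            seq[v.position : v.position] = list(v.alt)
    return "".join(seq)


# ---------------------------------------------------------------------------
# standard configurations


def default_variant_panel(effect: float = 0.0) -> tuple[PlantedVariant, ...]:
    """A panel at the rCRS positions highlighted by the association scan
    (all substitutions verified against the bundled reference), with
    carrier frequencies spanning the 1-99% prevalence band."""
    rows = [
        (93, "A", "G", 0.12), (1005, "T", "C", 0.08), (1824, "T", "C", 0.05),
        (3394, "T", "C", 0.10), (4491, "G", "A", 0.06), (7828, "A", "G", 0.05),
        (9814, "T", "C", 0.07), (10586, "G", "A", 0.05), (12338, "T", "C", 0.06),
        (13708, "G", "A", 0.09), (14308, "T", "C", 0.11), (14470, "T", "C", 0.04),
        (15218, "A", "G", 0.03), (16362, "T", "C", 0.30), (16399, "A", "G", 0.02),
    ]
    return tuple(
        PlantedVariant(p, r, a, f, effect if p == 14308 else 0.0)
        for p, r, a, f in rows
    )


def random_variant_panel(
    ref: MitoReference,
    n_variants: int,
    seed: int,
    freq_range: tuple[float, float] = (0.02, 0.9),
    effects: float | np.ndarray = 0.0,
) -> tuple[PlantedVariant, ...]:
    """Random transition substitutions at distinct non-N positions."""
    rng = np.random.default_rng(np.random.SeedSequence((int(seed), 0x5EED)))
    positions = []
    seen = set()
    while len(positions) < n_variants:
        pos = int(rng.integers(1, ref.length + 1))
        if pos in seen or ref.base(pos) not in "ACGT":
            continue
        seen.add(pos)
        positions.append(pos)
    freqs = rng.uniform(*freq_range, size=n_variants)
    eff = np.broadcast_to(np.asarray(effects, dtype=float), (n_variants,))
    return tuple(
        PlantedVariant(p, ref.base(p), _TRANSITION_PARTNER[ref.base(p)], f, e)
        for p, f, e in zip(positions, freqs, eff)
    )


def null_scan_config(
    ref: MitoReference,
    n_participants: int = 724,
    n_columns: int = 287,
    seed: int = 0,
) -> SimulationConfig:
    """A fully null scan dataset: every variant effect zero."""
    return SimulationConfig(
        n_participants=n_participants,
        variants=random_variant_panel(ref, n_columns, seed,
                                      freq_range=(0.02, 0.9)),
        ambiguity_rate=0.0,
        seed=seed,
    )


def planted_effect_config(
    ref: MitoReference,
    effect: float = -55.0,
    frequency: float = 0.10,
    n_participants: int = 724,
    n_null_columns: int = 29,
    seed: int = 0,
) -> SimulationConfig:
    """One causal substitution among null columns (power / recovery studies)."""
    panel = list(random_variant_panel(ref, n_null_columns + 1, seed,
                                      freq_range=(0.03, 0.5)))
    causal = replace(panel[0], frequency=frequency, effect=effect)
    return SimulationConfig(
        n_participants=n_participants,
        variants=tuple([causal] + panel[1:]),
        ambiguity_rate=0.0,
        seed=seed,
    )


def make_fixture_suite(ref: MitoReference, seed: int = 20_240) -> dict:
    """Standing small fixtures used across the test suite.

    Returns a dict with single genomes (identity, one substitution, an
    indel genome, an ambiguity genome), a 16-stratum mini-cohort with at
    least five Han participants per stratum, and scan configurations
    (null and planted-effect).
    """
    rcrs = ref.sequence
    single = apply_variants(rcrs, [Variant(1005, "T", "C", "substitution")])
    del_pos = left_align_deletion(rcrs, 8281, 9)
    ins_anchor, ins_bases = left_align_insertion(rcrs, 5899, "C")
    indel_truth = sorted(
        [
            Variant(4491, "G", "A", "substitution"),
            Variant(del_pos, rcrs[del_pos - 1 : del_pos + 8], "", "deletion"),
            Variant(ins_anchor, "", ins_bases, "insertion"),
        ]
    )
    indel = apply_variants(rcrs, indel_truth)
    ambiguity = apply_variants(rcrs, [Variant(93, "A", "R", "substitution")])

    strata_cohort = _strata_mini_cohort(ref, seed)

    return {
        "identity_genome": rcrs,
        "single_substitution_genome": single,
        "indel_genome": indel,
        "indel_genome_truth": indel_truth,
        "ambiguity_genome": ambiguity,
        "strata_cohort": strata_cohort,
        "null_scan_config": null_scan_config(ref, seed=seed),
        "planted_effect_config": planted_effect_config(ref, seed=seed),
    }


def _strata_mini_cohort(ref: MitoReference, seed: int) -> SyntheticCohort:
    """Deterministic 16-stratum cohort: 6 Han members per stratum plus 4
    minority participants (exercising the ethnicity filter)."""
    cfg = SimulationConfig(
        n_participants=100,
        variants=default_variant_panel(),
        ambiguity_rate=0.0,
        seed=seed,
    )
    cohort = simulate_cohort(cfg, ref, build_sequences=False)
    meta = cohort.metadata
    rows_per_stratum = 6
    i = 0
    for gender in ("male", "female"):
        for group, (lo, hi) in AGE_GROUP_RANGES.items():
            for immune, cd4 in (("severe", 150.0), ("mild", 300.0)):
                for k in range(rows_per_stratum):
                    meta.loc[i, ["gender", "age", "age_group", "ethnicity",
                                 "cd4_pre", "immune_level"]] = [
                        gender, lo + k, group, "Han", cd4 + k, immune,
                    ]
                    i += 1
    meta.loc[i:, "ethnicity"] = "minority"
    return cohort
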