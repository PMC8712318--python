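"""Cohort-level mutational characterization metrics.

All metrics operate on the expanded variant-type registry produced by
:mod:`mitocohort.calling` (one row per distinct variant type per
overlapping gene, with carrier counts).  The vocabulary:

diversity
    Number of distinct variant types in a unit (gene, macrodivision or
    whole genome).  A type inside two overlapping genes counts once in
    each gene but only once genome-wide.
volume
    Carrier-weighted count of variants (diversity == volume for a
    single participant).
diversity density
    diversity / sample size / unit length in kb.
relative diversity
    Distinct *definite* substitution types observed in the coding
    regions divided by all possible substitutions of the same class
    (synonymous / nonsynonymous / transition / transversion) enumerated
    from the reference and the mitochondrial genetic code.
relative diversity density
    Relative diversity with the observed count first divided by the
    sample size.
momentum
    The least-squares slope of per-gene (observed distinct definite
    types / sample size) against the per-gene maximum possible count,
    across the 13 protein-coding genes.
amino-acid change bias
    Observed distinct amino-acid changes to a target residue divided by
    the maximum possible changes to it.
physicochemical change prevalence
    Distribution of observed amino-acid changes over ordered pairs of
    property classes (acidity/polarity, hydropathy, volume, ...).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from .reference import STOP, MitoGeneticCode, MitoReference, SubstitutionSpace

TYPE_KEY = ["position", "ref", "alt", "kind"]

CLASS_COLUMNS = {
    "synonymous": "possible_synonymous",
    "nonsynonymous": "possible_nonsynonymous",
    "transition": "possible_transitions",
    "transversion": "possible_transversions",
}


def _unit_column(registry: pd.DataFrame, grouping: str) -> pd.Series:
    if grouping == "gene":
        return registry["gene"].fillna("intergenic")
    if grouping == "macrodivision":
        return registry["macrodivision"].fillna("intergenic")
    if grouping == "genome":
        return pd.Series("genome", index=registry.index)
    raise ValueError(f"unknown grouping {grouping!r}")


def diversity_and_volume(
    registry: pd.DataFrame, grouping: str = "macrodivision"
) -> pd.DataFrame:
    """Distinct-type and carrier-weighted counts per unit.

    Columns: ``diversity``/``volume`` over all variant kinds plus the
    ``substitution``, ``synonymous``, ``nonsynonymous`` (definite
    substitutions classified per gene) and ``indel`` class variants.
    """
    if registry.empty:
        raise ValueError("empty variant registry")
    reg = registry.copy()
    reg["unit"] = _unit_column(reg, grouping)
    # one row per (type, unit): a type spanning two genes of one
    # macrodivision (or the genome) must not double-count
    reg = reg.sort_values("synonymy").drop_duplicates(subset=TYPE_KEY + ["unit"])
    is_sub = reg["kind"] == "substitution"
    classes = {
        "": pd.Series(True, index=reg.index),
        "_substitution": is_sub,
        "_synonymous": reg["synonymy"].eq("synonymous"),
        "_nonsynonymous": reg["synonymy"].eq("nonsynonymous"),
        "_indel": ~is_sub,
    }
    out = {}
    for suffix, mask in classes.items():
        sel = reg[mask]
        out[f"diversity{suffix}"] = sel.groupby("unit").size()
        out[f"volume{suffix}"] = sel.groupby("unit")["carrier_count"].sum()
    table = pd.DataFrame(out).fillna(0).astype(int)
    table.index.name = grouping
    return table


def unit_lengths(ref: MitoReference, grouping: str = "macrodivision") -> pd.Series:
    """Unit sizes in bp (overlapping bases counted in each member gene)."""
    if grouping == "gene":
        return pd.Series({g: ref.gene_length(g) for g in ref.gene_names()})
    if grouping == "macrodivision":
        return pd.Series(
            {m: ref.macrodivision_length(m) for m in sorted(
                {f.macrodivision for f in ref.features})}
        )
    if grouping == "genome":
        return pd.Series({"genome": ref.length})
    raise ValueError(f"unknown grouping {grouping!r}")


def diversity_density(diversity, n_samples: int, unit_length_kb):
    """diversity / sample size / kilobases (vectorized over Series)."""
    if n_samples <= 0:
        raise ValueError("sample size must be positive")
    if np.any(np.asarray(unit_length_kb) <= 0):
        raise ValueError("unit length must be positive")
    return diversity / n_samples / unit_length_kb


def diversity_density_table(
    registry: pd.DataFrame,
    ref: MitoReference,
    n_samples: int,
    grouping: str = "macrodivision",
) -> pd.DataFrame:
    """Per-unit diversity densities for all classes (types /n /kb)."""
    table = diversity_and_volume(registry, grouping)
    lengths_kb = unit_lengths(ref, grouping) / 1000.0
    lengths_kb = lengths_kb.reindex(table.index)
    div_cols = [c for c in table.columns if c.startswith("diversity")]
    out = table[div_cols].div(n_samples).div(lengths_kb, axis=0)
    out.columns = [c.replace("diversity", "density") for c in div_cols]
    return out


# ---------------------------------------------------------------------------
# relative diversity and momentum


def observed_definite_counts(
    registry: pd.DataFrame, per_gene: bool = False
) -> pd.DataFrame | pd.Series:
    """Distinct definite substitution types in coding genes, by class.

    Counts are per protein-coding gene (``per_gene=True``) or summed over
    genes (overlap positions then counted once per gene, matching the
    possible-substitution totals).  Classes: all / synonymous /
    nonsynonymous / transition / transversion.
    """
    coding = registry[
        registry["definite"]
        & registry["synonymy"].isin(["synonymous", "nonsynonymous"])
    ]
    frames = {
        "all": coding,
        "synonymous": coding[coding["synonymy"] == "synonymous"],
        "nonsynonymous": coding[coding["synonymy"] == "nonsynonymous"],
        "transition": coding[coding["transition"].astype(bool)],
        "transversion": coding[~coding["transition"].astype(bool)],
    }
    counts = pd.DataFrame(
        {
            cls: frame.groupby("gene").size()
            for cls, frame in frames.items()
        }
    ).fillna(0).astype(int)
    if per_gene:
        return counts
    return counts.sum()


def relative_diversity(observed: int, possible: int) -> float:
    """observed / possible distinct definite substitutions of one class."""
    if possible < 0 or observed < 0:
        raise ValueError("counts must be nonnegative")
    if observed > possible:
        raise ValueError(
            f"observed ({observed}) exceeds possible ({possible}): "
            "classification bug upstream"
        )
    return observed / possible if possible else 0.0


def relative_diversity_table(
    registry: pd.DataFrame,
    space: SubstitutionSpace,
    n_samples: int | None = None,
) -> pd.DataFrame:
    """Genome-wide relative diversity (optionally density) per class."""
    observed = observed_definite_counts(registry)
    rows = {}
    for cls in ["all", "synonymous", "nonsynonymous", "transition", "transversion"]:
        possible = space.possible(cls)
        rel = relative_diversity(int(observed[cls]), possible)
        row = {"observed": int(observed[cls]), "possible": possible,
               "relative_diversity": rel}
        if n_samples:
            row["relative_diversity_density"] = rel / n_samples
        rows[cls] = row
    return pd.DataFrame(rows).T


@dataclass(frozen=True)
class MomentumResult:
    slope: float
    intercept: float
    r_squared: float
    p_value: float
    n_genes: int


def momentum(
    per_gene_observed: pd.Series,
    n_samples: int,
    space: SubstitutionSpace,
    cls: str = "synonymous",
) -> MomentumResult:
    """Slope of per-gene (observed definite types / n) on possible counts.

    Fitted by ordinary least squares with intercept across the
    protein-coding genes; ``per_gene_observed`` is indexed by gene and
    missing genes count as zero.
    """
    if n_samples <= 0:
        raise ValueError("sample size must be positive")
    possible = space.per_gene[CLASS_COLUMNS[cls]]
    y = per_gene_observed.reindex(possible.index).fillna(0.0) / n_samples
    x = possible.astype(float)
    if len(x) < 3:
        raise ValueError("momentum needs at least 3 genes")
    if float(x.max() - x.min()) == 0.0:
        raise ValueError("degenerate regressor: possible counts all equal")
    fit = stats.linregress(x.to_numpy(), y.to_numpy())
    return MomentumResult(
        slope=float(fit.slope),
        intercept=float(fit.intercept),
        r_squared=float(fit.rvalue) ** 2,
        p_value=float(fit.pvalue),
        n_genes=len(x),
    )


# ---------------------------------------------------------------------------
# amino-acid changes


@dataclass
class AminoAcidChangeMatrix:
    """Observed amino-acid replacement counts with bias denominators.

    ``observed`` is a (source aa x target aa) count matrix over the 20
    standard residues, derived from distinct definite nonsynonymous
    substitution types (stop-gain/-loss changes are excluded: they do
    not produce a target residue pair).  ``bias`` divides the observed
    changes *to* each residue by the maximum possible changes to it;
    ``bias_density`` additionally divides the observed count by the
    sample size.
    """

    observed: pd.DataFrame
    bias: pd.Series
    bias_density: pd.Series | None
    n_samples: int | None

    @property
    def most_prevalent(self) -> tuple[str, str, int]:
        flat = self.observed.stack()
        (src, dst), count = flat.idxmax(), int(flat.max())
        return src, dst, count


def amino_acid_changes(
    registry: pd.DataFrame,
    space: SubstitutionSpace,
    n_samples: int | None = None,
    carrier_weighted: bool = False,
) -> AminoAcidChangeMatrix:
    """Tally amino-acid replacements from the nonsynonymous registry rows.

    A "change" is a distinct definite nonsynonymous substitution type in
    one gene; by default each type counts once (``carrier_weighted``
    counts carriers instead).
    """
    aas = list(space.max_changes_to_aa.index)
    rows = registry[
        registry["definite"]
        & registry["synonymy"].eq("nonsynonymous")
        & registry["aa_ref"].notna()
        & registry["aa_alt"].notna()
        & ~registry["aa_ref"].eq(STOP)
        & ~registry["aa_alt"].eq(STOP)
    ]
    observed = pd.DataFrame(0, index=aas, columns=aas, dtype=int)
    weights = rows["carrier_count"] if carrier_weighted else 1
    grouped = rows.assign(w=weights).groupby(["aa_ref", "aa_alt"])["w"].sum()
    for (src, dst), count in grouped.items():
        observed.loc[src, dst] = int(count)
    if int(np.diag(observed.to_numpy()).sum()) != 0:
        raise AssertionError("diagonal of the change matrix must be zero")
    to_counts = observed.sum(axis=0)
    denom = space.max_changes_to_aa.reindex(aas)
    bias = (to_counts / denom).astype(float)
    density = (to_counts / n_samples / denom).astype(float) if n_samples else None
    return AminoAcidChangeMatrix(
        observed=observed, bias=bias, bias_density=density, n_samples=n_samples
    )


def physicochemical_changes(
    matrix: AminoAcidChangeMatrix,
    code: MitoGeneticCode,
    scheme: str = "acidity",
    n_samples: int | None = None,
) -> pd.DataFrame:
    """Prevalence of ordered property-class pairs among observed changes.

    Returns one row per ordered (from_class, to_class) pair with its
    count, percentage of all observed changes (summing to 100), and,
    given a sample size, the count divided by it.
    """
    classes = code.property_schemes.get(scheme)
    if classes is None:
        raise ValueError(
            f"unknown property scheme {scheme!r}; "
            f"available: {sorted(code.property_schemes)}"
        )
    counts: dict[tuple[str, str], int] = {}
    for src in matrix.observed.index:
        for dst in matrix.observed.columns:
            n = int(matrix.observed.loc[src, dst])
            if n:
                key = (classes[src], classes[dst])
                counts[key] = counts.get(key, 0) + n
    total = sum(counts.values())
    rows = [
        {
            "from_class": a,
            "to_class": b,
            "count": n,
            "percent": 100.0 * n / total if total else 0.0,
        }
        for (a, b), n in sorted(counts.items())
    ]
    table = pd.DataFrame(rows, columns=["from_class", "to_class", "count", "percent"])
    if n_samples:
        table["density"] = table["count"] / n_samples
    return table
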