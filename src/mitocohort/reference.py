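"""The human mitochondrial reference genome and its substitution space.

This module owns everything that is a fixed property of the revised
Cambridge Reference Sequence (rCRS, GenBank NC_012920.1): the 16,569-bp
circular sequence, the 37-gene annotation plus the control region, the
seven-way macrodivision grouping used for regional summaries (D-loop,
RNRs, tRNAs, NDs, COs, ATPs, CYB), the vertebrate mitochondrial genetic
code (NCBI translation table 2), and the enumeration of every possible
single-nucleotide substitution over the 13 protein-coding genes,
classified as synonymous or nonsynonymous and as transition or
transversion.

The possible-substitution space is the denominator of the cohort-level
"relative diversity" and "momentum" statistics, and the per-amino-acid
maxima it produces are the denominators of amino-acid-change bias.
Enumeration conventions (how gene overlaps, incomplete stop codons and
initiator codons are treated) are explicit keyword switches on
:func:`enumerate_substitution_space`; the defaults are the calibrated
conventions under which the bundled rCRS yields 8,291 possible
synonymous and 25,894 possible nonsynonymous substitutions.
"""

from __future__ import annotations

import importlib.resources
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml
from Bio import SeqIO
from Bio.Data.CodonTable import unambiguous_dna_by_id

RCRS_LENGTH = 16569

#: Nucleotides considered definite calls.
DEFINITE_BASES = frozenset("ACGT")

#: IUPAC ambiguity codes and the definite bases they stand for.
IUPAC_AMBIGUITY = {
    "R": "AG", "Y": "CT", "S": "CG", "W": "AT", "K": "GT", "M": "AC",
    "B": "CGT", "D": "AGT", "H": "ACT", "V": "ACG", "N": "ACGT",
}

_COMPLEMENT = str.maketrans("ACGTNRYSWKMBDHV", "TGCANYRSWMKVHDB")

MACRODIVISIONS = ("D-loop", "RNRs", "tRNAs", "NDs", "COs", "ATPs", "CYB")

PURINES = frozenset("AG")

STOP = "*"


class ReferenceError(ValueError):
    """A reference FASTA or feature table failed validation."""


class UntranslatableCodonError(ValueError):
    """Codon contains a base outside {A, C, G, T}."""


def reverse_complement(seq: str) -> str:
    return seq.translate(_COMPLEMENT)[::-1]


def is_transition(ref: str, alt: str) -> bool:
    """Purine<->purine or pyrimidine<->pyrimidine change (A<->G, C<->T)."""
    return (ref in PURINES) == (alt in PURINES)


@dataclass(frozen=True)
class GeneFeature:
    """One annotated feature on the rCRS (1-based inclusive coordinates).

    ``incomplete_stop`` is the number of trailing genome-encoded bases
    (0-2) of a stop codon that is completed by 3' polyadenylation of the
    mRNA (the T/TA endings of ND1, ND2, CO3, ND3, ND4 and CYB).
    """

    name: str
    start: int
    end: int
    strand: str  # "H" (heavy) | "L" (light)
    kind: str    # "protein" | "tRNA" | "rRNA" | "control"
    incomplete_stop: int
    macrodivision: str

    @property
    def length(self) -> int:
        return self.end - self.start + 1

    def __post_init__(self) -> None:
        if self.strand not in ("H", "L"):
            raise ReferenceError(f"{self.name}: strand must be H or L")
        if self.kind == "protein" and (self.length - self.incomplete_stop) % 3:
            raise ReferenceError(
                f"{self.name}: coding length {self.length} minus "
                f"{self.incomplete_stop} trailing bases is not divisible by 3"
            )


class MitoGeneticCode:
    """Vertebrate mitochondrial genetic code (NCBI table 2).

    Differs from the universal code at four codons: AGA/AGG are stops,
    ATA is Met and TGA is Trp.  Also carries the amino-acid
    physicochemical class schemes used for substitution-effect profiling
    (acidity/polarity classes plus the IMGT-style hydropathy, volume,
    chemical, charge, hydrogen donor/acceptor and polarity partitions).
    """

    def __init__(self) -> None:
        table = unambiguous_dna_by_id[2]
        self.codon_table: dict[str, str] = dict(table.forward_table)
        self.stop_codons: frozenset[str] = frozenset(table.stop_codons)
        for codon in self.stop_codons:
            self.codon_table[codon] = STOP
        if len(self.codon_table) != 64:
            raise AssertionError("mitochondrial code must map all 64 codons")
        self.amino_acids: tuple[str, ...] = tuple(
            sorted(set(self.codon_table.values()) - {STOP})
        )
        self.property_schemes: dict[str, dict[str, str]] = _load_schemes()

    def translate(self, codon: str) -> str:
        """Translate a 3-mer; returns ``"*"`` for a stop codon.

        Raises :class:`UntranslatableCodonError` if the codon contains an
        ambiguous or invalid base.
        """
        codon = codon.upper()
        aa = self.codon_table.get(codon)
        if aa is None:
            raise UntranslatableCodonError(f"untranslatable codon {codon!r}")
        return aa

    def aa_class(self, aa: str, scheme: str) -> str:
        try:
            classes = self.property_schemes[scheme]
        except KeyError:
            raise KeyError(
                f"unknown property scheme {scheme!r}; "
                f"available: {sorted(self.property_schemes)}"
            ) from None
        return classes[aa]


def _load_schemes() -> dict[str, dict[str, str]]:
    path = importlib.resources.files("mitocohort") / "data" / "aa_class_schemes.yaml"
    raw = yaml.safe_load(path.read_text())
    schemes: dict[str, dict[str, str]] = {}
    for scheme, classes in raw.items():
        mapping: dict[str, str] = {}
        for cls, aas in classes.items():
            for aa in aas:
                if aa in mapping:
                    raise AssertionError(f"{scheme}: {aa} in two classes")
                mapping[aa] = cls
        if len(mapping) != 20:
            raise AssertionError(f"{scheme}: classes must partition 20 amino acids")
        schemes[scheme] = mapping
    return schemes


def translate_codon(codon: str, code: MitoGeneticCode) -> str:
    """Vertebrate-mitochondrial translation of one codon ("*" = stop)."""
    return code.translate(codon)


@dataclass
class MitoReference:
    """The rCRS sequence plus annotation and position->feature index."""

    sequence: str
    features: list[GeneFeature]
    code: MitoGeneticCode = field(default_factory=MitoGeneticCode)

    def __post_init__(self) -> None:
        self.length = len(self.sequence)
        # position -> features covering it (1-based; multiple in overlaps)
        index: list[list[GeneFeature]] = [[] for _ in range(self.length + 1)]
        for feat in self.features:
            for pos in range(feat.start, feat.end + 1):
                index[pos].append(feat)
        self._position_index = index
        self.macrodivisions: dict[str, str] = {
            f.name: f.macrodivision for f in self.features
        }

    # -- lookups ---------------------------------------------------------

    def base(self, position: int) -> str:
        """Reference base at a 1-based position."""
        if not 1 <= position <= self.length:
            raise IndexError(f"position {position} outside 1..{self.length}")
        return self.sequence[position - 1]

    def features_at(self, position: int) -> list[GeneFeature]:
        if not 1 <= position <= self.length:
            raise IndexError(f"position {position} outside 1..{self.length}")
        return list(self._position_index[position])

    def feature(self, name: str) -> GeneFeature:
        for feat in self.features:
            if feat.name == name:
                return feat
        raise KeyError(name)

    @property
    def protein_genes(self) -> list[GeneFeature]:
        return [f for f in self.features if f.kind == "protein"]

    def gene_names(self, kind: str | None = None) -> list[str]:
        seen: dict[str, None] = {}
        for f in self.features:
            if kind is None or f.kind == kind:
                seen.setdefault(f.name)
        return list(seen)

    def gene_length(self, name: str) -> int:
        """Total genomic span of a gene in bp (control-region arcs summed)."""
        return sum(f.length for f in self.features if f.name == name)

    def macrodivision_length(self, macrodivision: str) -> int:
        """Summed length of member genes (overlapping bases counted per gene)."""
        return sum(f.length for f in self.features if f.macrodivision == macrodivision)

    # -- coding-sequence machinery ---------------------------------------

    def coding_sequence(self, feature: GeneFeature, completed: bool = True) -> str:
        """mRNA-sense CDS of a protein gene.

        Light-strand genes are reverse-complemented.  With ``completed``
        the polyadenylation-completed stop codon is padded with 3' A's so
        the result is always a whole number of codons.
        """
        if feature.kind != "protein":
            raise ValueError(f"{feature.name} is not protein-coding")
        cds = self.sequence[feature.start - 1 : feature.end]
        if feature.strand == "L":
            cds = reverse_complement(cds)
        if completed and feature.incomplete_stop:
            cds += "A" * (3 - feature.incomplete_stop)
        return cds

    def cds_offset(self, feature: GeneFeature, position: int) -> int:
        """0-based offset of a genomic position within a gene's mRNA-sense CDS."""
        if not feature.start <= position <= feature.end:
            raise ValueError(f"position {position} not inside {feature.name}")
        if feature.strand == "L":
            return feature.end - position
        return position - feature.start

    def classify_substitution(
        self,
        feature: GeneFeature,
        position: int,
        alt: str,
        *,
        completed_stop_tga_synonymous: bool = True,
        initiator_as_met: bool = False,
    ) -> tuple[int, str, str, bool]:
        """Effect of a definite substitution on one protein gene.

        Returns ``(codon_number, aa_ref, aa_alt, synonymous)`` with the
        codon number 1-based.  ``alt`` is given on the heavy strand (the
        strand of the reference sequence) and is complemented internally
        for light-strand genes.

        Conventions (see the enumeration docstring): incomplete stop
        codons are completed with 3' A's before translation; with
        ``completed_stop_tga_synonymous`` a completed stop codon mutating
        to TGA still terminates translation and the change is counted
        synonymous; with ``initiator_as_met`` the first codon is read as
        Met and a mutation there is synonymous iff the mutated codon is
        also a mitochondrial initiator (ATG/ATA/ATT/GTG).
        """
        if alt not in DEFINITE_BASES:
            raise ValueError(f"alt {alt!r} is not a definite base")
        cds = self.coding_sequence(feature, completed=True)
        offset = self.cds_offset(feature, position)
        if feature.strand == "L":
            alt = alt.translate(_COMPLEMENT)
        codon_idx, within = divmod(offset, 3)
        codon = cds[codon_idx * 3 : codon_idx * 3 + 3]
        mutated = codon[:within] + alt + codon[within + 1 :]
        aa_ref = self.code.translate(codon)
        aa_alt = self.code.translate(mutated)
        synonymous = aa_alt == aa_ref
        is_completed_stop = (
            feature.incomplete_stop > 0 and codon_idx == len(cds) // 3 - 1
        )
        if (
            completed_stop_tga_synonymous
            and is_completed_stop
            and aa_ref == STOP
            and mutated == "TGA"
        ):
            synonymous = True
        if initiator_as_met and codon_idx == 0:
            aa_ref = "M"
            aa_alt = "M" if mutated in ("ATG", "ATA", "ATT", "GTG") else aa_alt
            synonymous = aa_alt == aa_ref
        return codon_idx + 1, aa_ref, aa_alt, synonymous

    def region_of(self, position: int) -> list[tuple[str, str]]:
        """All (gene, macrodivision) pairs covering a 1-based position.

        Positions inside two overlapping genes return both; intergenic
        positions return an empty list.
        """
        seen: dict[tuple[str, str], None] = {}
        for feat in self.features_at(position):
            seen.setdefault((feat.name, feat.macrodivision))
        return list(seen)


def region_of(position: int, ref: MitoReference) -> list[tuple[str, str]]:
    """Functional alias of :meth:`MitoReference.region_of`."""
    return ref.region_of(position)


# ---------------------------------------------------------------------------
# loading


def _bundled(name: str) -> Path:
    return Path(str(importlib.resources.files("mitocohort") / "data" / name))


def load_reference(
    reference_fasta: str | Path | None = None,
    feature_table: str | Path | None = None,
) -> MitoReference:
    """Load and validate the rCRS plus its gene-feature table.

    With no arguments the bundled NC_012920.1 fixture and annotation are
    used.  The feature table is tab-delimited with columns
    ``gene, start, end, strand, kind, incomplete_stop, macrodivision``;
    the wrap-around control region is represented as two arcs sharing the
    name ``D-loop``.
    """
    fasta_path = Path(reference_fasta) if reference_fasta else _bundled("rCRS.fasta")
    table_path = Path(feature_table) if feature_table else _bundled("rcrs_features.tsv")

    records = list(SeqIO.parse(str(fasta_path), "fasta"))
    if len(records) != 1:
        raise ReferenceError(
            f"reference FASTA must contain exactly one record, found {len(records)}"
        )
    sequence = str(records[0].seq).upper()
    if len(sequence) != RCRS_LENGTH:
        raise ReferenceError(
            f"reference length mismatch: expected {RCRS_LENGTH}, got {len(sequence)}"
        )
    bad = [
        (i + 1, b) for i, b in enumerate(sequence) if b not in "ACGTN"
    ]
    if bad:
        pos, base = bad[0]
        raise ReferenceError(
            f"invalid nucleotide {base!r} at position {pos} "
            f"({len(bad)} invalid positions in total)"
        )

    table = pd.read_csv(table_path, sep="\t", dtype={"gene": str})
    required = {"gene", "start", "end", "strand", "kind", "incomplete_stop",
                "macrodivision"}
    missing_cols = required - set(table.columns)
    if missing_cols:
        raise ReferenceError(f"feature table missing columns: {sorted(missing_cols)}")
    features = [
        GeneFeature(
            name=row.gene,
            start=int(row.start),
            end=int(row.end),
            strand=row.strand,
            kind=row.kind,
            incomplete_stop=int(row.incomplete_stop),
            macrodivision=row.macrodivision,
        )
        for row in table.itertuples()
    ]
    for feat in features:
        if not (1 <= feat.start <= feat.end <= len(sequence)):
            raise ReferenceError(
                f"{feat.name}: coordinates {feat.start}-{feat.end} outside reference"
            )
        if feat.macrodivision not in MACRODIVISIONS:
            raise ReferenceError(
                f"{feat.name}: unknown macrodivision {feat.macrodivision!r}"
            )

    names = {f.name for f in features}
    n_protein = len({f.name for f in features if f.kind == "protein"})
    n_trna = len({f.name for f in features if f.kind == "tRNA"})
    n_rrna = len({f.name for f in features if f.kind == "rRNA"})
    expected_protein = {
        "ND1", "ND2", "CO1", "CO2", "ATP8", "ATP6", "CO3", "ND3", "ND4L",
        "ND4", "ND5", "ND6", "CYB",
    }
    missing = expected_protein - names
    if "D-loop" not in names:
        missing.add("D-loop")
    if missing:
        raise ReferenceError(f"feature table missing genes: {sorted(missing)}")
    if (n_protein, n_trna, n_rrna) != (13, 22, 2):
        raise ReferenceError(
            "feature table must annotate 13 protein genes, 22 tRNAs and 2 "
            f"rRNAs; found {n_protein}/{n_trna}/{n_rrna}"
        )

    ref = MitoReference(sequence=sequence, features=features)
    # the seven macrodivisions must jointly cover all genes + control region
    covered = {f.macrodivision for f in features}
    if covered != set(MACRODIVISIONS):
        raise ReferenceError(f"macrodivisions incomplete: {sorted(covered)}")
    return ref


# ---------------------------------------------------------------------------
# substitution space


@dataclass
class SubstitutionSpace:
    """All possible single-base substitutions over the protein-coding genes.

    ``per_gene`` is indexed by gene with columns ``coding_positions``,
    ``possible_synonymous``, ``possible_nonsynonymous``,
    ``possible_transitions`` and ``possible_transversions``; ``totals``
    aggregates genome-wide (positions shared by overlapping genes counted
    once per gene, i.e. twice in the totals, per the calibrated
    convention).  ``max_changes_to_aa`` gives, for each target amino
    acid, the number of possible nonsynonymous changes producing it --
    the denominator of amino-acid-change bias.  ``aa_change_max`` is the
    full (ref aa x new aa) matrix of possible-change counts.
    """

    per_gene: pd.DataFrame
    totals: pd.Series
    max_changes_to_aa: pd.Series
    aa_change_max: pd.DataFrame
    conventions: dict[str, bool]

    def possible(self, cls: str, gene: str | None = None) -> int:
        """Possible-substitution count for a class, per gene or genome-wide.

        ``cls`` is one of ``all, synonymous, nonsynonymous, transition,
        transversion``.
        """
        col = {
            "all": None,
            "synonymous": "possible_synonymous",
            "nonsynonymous": "possible_nonsynonymous",
            "transition": "possible_transitions",
            "transversion": "possible_transversions",
        }[cls]
        row = self.totals if gene is None else self.per_gene.loc[gene]
        if col is None:
            return int(row["possible_synonymous"] + row["possible_nonsynonymous"])
        return int(row[col])


def enumerate_substitution_space(
    ref: MitoReference,
    *,
    completed_stop_tga_synonymous: bool = True,
    include_incomplete_stop_positions: bool = True,
    initiator_as_met: bool = False,
) -> SubstitutionSpace:
    """Classify every possible substitution at every protein-coding position.

    For each genome-encoded position of each of the 13 protein-coding
    genes and each of the 3 alternative bases, the change is classified
    as synonymous or nonsynonymous by re-translating the affected codon
    under the vertebrate mitochondrial code (light-strand genes are
    reverse-complemented first) and as transition or transversion.

    Conventions, all explicit and calibrated so the bundled rCRS yields
    8,291 possible synonymous and 25,894 possible nonsynonymous
    substitutions genome-wide:

    * positions inside two overlapping genes contribute to each gene
      independently, and gene overlaps are double-counted in the totals;
    * incomplete stop codons are completed with 3' A's (polyadenylation)
      and their genome-encoded positions are included;
    * a completed stop codon mutating to TGA is counted synonymous
      (``completed_stop_tga_synonymous``) -- the single such change on
      the rCRS is the A of ND1's TA ending;
    * substitutions creating or destroying a stop codon are
      nonsynonymous; stop-to-stop changes are synonymous;
    * initiator codons are translated by the plain table unless
      ``initiator_as_met`` is set.

    The rCRS placeholder N at position 3107 lies in RNR2 and therefore
    never enters the space; an N inside a CDS would be skipped.
    """
    aas = list(ref.code.amino_acids) + [STOP]
    aa_index = {aa: i for i, aa in enumerate(aas)}
    change_max = np.zeros((len(aas), len(aas)), dtype=int)
    rows = []
    for feat in ref.protein_genes:
        syn = nsyn = ts = tv = positions = 0
        n_skip = feat.incomplete_stop if not include_incomplete_stop_positions else 0
        if feat.strand == "H":
            genomic = range(feat.start, feat.end + 1 - n_skip)
        else:
            genomic = range(feat.start + n_skip, feat.end + 1)
        for pos in genomic:
            base = ref.base(pos)
            if base not in DEFINITE_BASES:
                continue
            positions += 1
            for alt in "ACGT":
                if alt == base:
                    continue
                _, aa_ref, aa_alt, synonymous = ref.classify_substitution(
                    feat, pos, alt,
                    completed_stop_tga_synonymous=completed_stop_tga_synonymous,
                    initiator_as_met=initiator_as_met,
                )
                if synonymous:
                    syn += 1
                else:
                    nsyn += 1
                    change_max[aa_index[aa_ref], aa_index[aa_alt]] += 1
                if is_transition(base, alt):
                    ts += 1
                else:
                    tv += 1
        rows.append(
            {
                "gene": feat.name,
                "coding_positions": positions,
                "possible_synonymous": syn,
                "possible_nonsynonymous": nsyn,
                "possible_transitions": ts,
                "possible_transversions": tv,
            }
        )
    per_gene = pd.DataFrame(rows).set_index("gene")
    totals = per_gene.sum()
    aa_change_max = pd.DataFrame(change_max, index=aas, columns=aas)
    max_to_aa = aa_change_max.drop(index=STOP, errors="ignore").sum(axis=0)
    max_to_aa = max_to_aa.drop(labels=[STOP], errors="ignore")
    return SubstitutionSpace(
        per_gene=per_gene,
        totals=totals,
        max_changes_to_aa=max_to_aa,
        aa_change_max=aa_change_max,
        conventions={
            "completed_stop_tga_synonymous": completed_stop_tga_synonymous,
            "include_incomplete_stop_positions": include_incomplete_stop_positions,
            "initiator_as_met": initiator_as_met,
        },
    )
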