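"""Deliberately naive metric recomputations used only as test oracles.

Everything here works directly from per-sample variant lists with plain
dict/set bookkeeping, independent of the pandas-based implementations in
:mod:`mitocohort.metrics`.
"""

from collections import Counter


def naive_diversity_volume(per_sample, unit_of):
    """unit -> (diversity, volume) from per-sample (variant, annotation)
    pairs; ``unit_of(variant, annotation)`` yields the unit labels."""
    types_per_unit = {}
    volume_per_unit = Counter()
    for calls in per_sample.values():
        for v, ann in calls:
            key = (v.position, v.ref, v.alt, v.kind)
            for unit in set(unit_of(v, ann)):
                types_per_unit.setdefault(unit, set()).add(key)
                volume_per_unit[unit] += 1
    return {
        u: (len(types_per_unit[u]), volume_per_unit[u]) for u in types_per_unit
    }


def naive_definite_class_counts(per_sample):
    """Distinct definite coding substitution types per class, summed over
    genes (a type in two genes counts once per gene)."""
    seen = set()
    for calls in per_sample.values():
        for v, ann in calls:
            if not ann.definite:
                continue
            for eff in ann.genes:
                if eff.synonymy in ("synonymous", "nonsynonymous"):
                    seen.add(
                        (v.position, v.ref, v.alt, eff.gene, eff.synonymy,
                         ann.transition)
                    )
    counts = {"all": len(seen), "synonymous": 0, "nonsynonymous": 0,
              "transition": 0, "transversion": 0}
    for *_, synonymy, transition in seen:
        counts[synonymy] += 1
        counts["transition" if transition else "transversion"] += 1
    return counts


def naive_aa_change_counts(per_sample):
    """(aa_ref, aa_alt) -> distinct definite nonsynonymous type count."""
    seen = set()
    for calls in per_sample.values():
        for v, ann in calls:
            if not ann.definite:
                continue
            for eff in ann.genes:
                if (
                    eff.synonymy == "nonsynonymous"
                    and eff.aa_ref not in (None, "*")
                    and eff.aa_alt not in (None, "*")
                ):
                    seen.add(
                        (v.position, v.ref, v.alt, eff.gene, eff.aa_ref,
                         eff.aa_alt)
                    )
    counts = Counter()
    for *_, aa_ref, aa_alt in seen:
        counts[(aa_ref, aa_alt)] += 1
    return dict(counts)
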