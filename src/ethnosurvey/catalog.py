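"""Documented use catalogue for *Synsepalum dulcificum* in Benin and Ghana.

Each entry records one documented use (or one body system pooling several
ailments): its use category, ICPC2-derived body system, the number of
citations recorded in the source survey, and the set of plant parts the
respondents employed for it.  The catalogue drives two things:

* the synthetic generator's within-category use weights and admissible
  plant-part lists, and
* the informant-agreement worked examples, where the agreement ratio is
  recomputed from each entry's citation count and part-list length.
"""

from __future__ import annotations

from dataclasses import dataclass


@dataclass(frozen=True)
class UseEntry:
    label: str
    category: str
    body_system: str        # "non_medicinal" outside the medicinal category
    citations: int          # documented citation count
    parts: tuple[str, ...]  # admissible plant parts


USE_CATALOG: tuple[UseEntry, ...] = (
    # food
    UseEntry("sweetener", "food", "non_medicinal", 497, ("fruit",)),
    # sales
    UseEntry("commercialization", "sales", "non_medicinal", 112,
             ("fruit", "leaf", "root", "seed", "twig")),
    # social
    UseEntry("chewing_stick", "social", "non_medicinal", 117, ("twig",)),
    UseEntry("hoe_handle", "social", "non_medicinal", 1, ("twig",)),
    UseEntry("harmony", "social", "non_medicinal", 10,
             ("fruit", "leaf", "root", "seed", "twig")),
    # magico-spiritual
    UseEntry("lucky_charm", "magico_spiritual", "non_medicinal", 95,
             ("flower", "fruit", "leaf", "root", "twig")),
    UseEntry("woe_induction", "magico_spiritual", "non_medicinal", 21,
             ("seed", "leaf", "fruit", "twig")),
    UseEntry("bewitchment", "magico_spiritual", "non_medicinal", 15,
             ("leaf", "root", "seed", "twig")),
    UseEntry("protection", "magico_spiritual", "non_medicinal", 13,
             ("leaf", "root", "twig")),
    UseEntry("love_attraction", "magico_spiritual", "non_medicinal", 12,
             ("fruit", "leaf", "twig")),
    UseEntry("wealth_attraction", "magico_spiritual", "non_medicinal", 8,
             ("fruit", "leaf", "root", "twig")),
    UseEntry("ritualistic", "magico_spiritual", "non_medicinal", 12,
             ("fruit", "leaf", "root")),
    # medicinal, one entry per body system (ailments pooled)
    UseEntry("anaemia", "medicinal", "blood", 3, ("leaf",)),
    UseEntry("circulatory_ailment", "medicinal", "circulatory", 22,
             ("bark", "leaf", "root", "seed")),
    UseEntry("digestive_ailment", "medicinal", "digestive", 90,
             ("bark", "fruit", "leaf", "root", "seed", "twig")),
    UseEntry("endocrine_ailment", "medicinal", "endocrine_metabolic_nutritional",
             18, ("fruit", "leaf", "root", "seed")),
    UseEntry("eye_pain", "medicinal", "eye", 2, ("fruit", "leaf")),
    UseEntry("female_genital_ailment", "medicinal", "female_genital", 9,
             ("leaf", "root")),
    UseEntry("general_health_ailment", "medicinal", "general_health", 68,
             ("bark", "fruit", "leaf", "root", "seed")),
    UseEntry("male_genital_ailment", "medicinal", "male_genital", 35,
             ("bark", "fruit", "leaf", "root", "seed", "twig")),
    UseEntry("musculoskeletal_ailment", "medicinal", "musculoskeletal", 6,
             ("leaf", "root")),
    UseEntry("neurological_ailment", "medicinal", "neurological", 6,
             ("fruit", "leaf")),
    UseEntry("pregnancy_ailment", "medicinal", "pregnancy_childbearing", 20,
             ("bark", "fruit", "leaf", "root")),
    UseEntry("psychological_ailment", "medicinal", "psychological", 20,
             ("bark", "flower", "fruit", "leaf", "root")),
    UseEntry("respiratory_ailment", "medicinal", "respiratory", 10,
             ("bark", "fruit", "leaf", "root")),
    UseEntry("skin_ailment", "medicinal", "skin", 6, ("bark", "leaf", "root")),
    UseEntry("urinary_ailment", "medicinal", "urinary", 26, ("leaf", "root")),
    # firewood
    UseEntry("firewood", "firewood", "non_medicinal", 1, ("twig",)),
)


def entries_for_category(category: str) -> tuple[UseEntry, ...]:
    return tuple(e for e in USE_CATALOG if e.category == category)


def entry_by_label(label: str) -> UseEntry:
    for e in USE_CATALOG:
        if e.label == label:
            return e
    raise KeyError(label)
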