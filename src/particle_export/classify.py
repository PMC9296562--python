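"""Trophic-mode and functional-group classification of ASV lineages.

Each ASV is assigned ``phytoplankton`` or ``heterotroph`` from its ranked
PR2-style lineage by prefix-token rules.  Two rules carry special
precedence, reflecting the plasticity of dinoflagellate trophic strategies
and the distinct ecology of diatoms:

* every Dinoflagellata (rank 3) that is not Syndiniales (rank 4) counts as
  phytoplankton; Syndiniales are heterotrophs;
* Bacillariophyta (diatoms, rank 4) form their own functional group,
  separate from the remaining Ochrophyta.

The rule set is data, not code: it can be loaded from a YAML config so the
photosynthetic-lineage list stays auditable and swappable.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import yaml

from .io import ASVDataset, N_RANKS

PHYTOPLANKTON = "phytoplankton"
HETEROTROPH = "heterotroph"

GENUS_RANK = 7  # PR2 v4: kingdom, supergroup, division, class, order, family, genus, species
CLASS_RANK = 4


@dataclass(frozen=True)
class Rule:
    """Match ``token`` at 1-based ``rank_index`` -> (trophic_mode, functional_group)."""

    rank_index: int
    token: str
    trophic_mode: str
    functional_group: str


@dataclass
class RuleSet:
    """Ordered special cases, then photosynthetic rules, then heterotroph groups.

    ``special_cases`` are evaluated first in order (Syndiniales must beat the
    Dinoflagellata rule).  Any lineage matching nothing is a heterotroph in
    ``fallback_group``.
    """

    special_cases: list[Rule] = field(default_factory=list)
    photo_rules: list[Rule] = field(default_factory=list)
    heterotroph_rules: list[Rule] = field(default_factory=list)
    fallback_group: str = "Other_heterotroph"

    def match(self, ranks: list[str]) -> tuple[str, str]:
        for rule in self.special_cases:
            if ranks[rule.rank_index - 1] == rule.token:
                return rule.trophic_mode, rule.functional_group
        for rule in self.photo_rules:
            if ranks[rule.rank_index - 1] == rule.token:
                return rule.trophic_mode, rule.functional_group
        for rule in self.heterotroph_rules:
            if ranks[rule.rank_index - 1] == rule.token:
                return HETEROTROPH, rule.functional_group
        return HETEROTROPH, self.fallback_group


def default_rules() -> RuleSet:
    """Photosynthetic groups as named in the export analyses.

    The list covers the functional groups used throughout: Bacillariophyta
    (assessed separately), Other_Ochrophyta, Dinoflagellata (minus
    Syndiniales), Chlorophyta and Hacrobia; heterotroph supergroups map to
    Opisthokonta, Rhizaria and Alveolata_other.
    """
    return RuleSet(
        special_cases=[
            Rule(4, "Syndiniales", HETEROTROPH, "Alveolata_other"),
            Rule(4, "Bacillariophyta", PHYTOPLANKTON, "Bacillariophyta"),
        ],
        photo_rules=[
            Rule(3, "Dinoflagellata", PHYTOPLANKTON, "Dinoflagellata"),
            Rule(3, "Ochrophyta", PHYTOPLANKTON, "Other_Ochrophyta"),
            Rule(3, "Chlorophyta", PHYTOPLANKTON, "Chlorophyta"),
            Rule(2, "Hacrobia", PHYTOPLANKTON, "Hacrobia"),
        ],
        heterotroph_rules=[
            Rule(2, "Opisthokonta", HETEROTROPH, "Opisthokonta"),
            Rule(2, "Rhizaria", HETEROTROPH, "Rhizaria"),
            Rule(2, "Alveolata", HETEROTROPH, "Alveolata_other"),
        ],
    )


def load_rules(path) -> RuleSet:
    """Load a RuleSet from a YAML config.

    Schema::

        special_cases:
          - {rank: 4, token: Syndiniales, trophic_mode: heterotroph, group: Alveolata_other}
        photosynthetic:
          - {rank: 3, token: Dinoflagellata, group: Dinoflagellata}
        heterotroph_groups:
          - {rank: 2, token: Opisthokonta, group: Opisthokonta}
        fallback_group: Other_heterotroph
    """
    payload = yaml.safe_load(open(path))
    def to_rule(entry, default_mode):
        return Rule(
            rank_index=int(entry["rank"]),
            token=str(entry["token"]).strip(),
            trophic_mode=entry.get("trophic_mode", default_mode),
            functional_group=str(entry["group"]),
        )
    return RuleSet(
        special_cases=[to_rule(e, HETEROTROPH) for e in payload.get("special_cases", [])],
        photo_rules=[to_rule(e, PHYTOPLANKTON) for e in payload.get("photosynthetic", [])],
        heterotroph_rules=[to_rule(e, HETEROTROPH) for e in payload.get("heterotroph_groups", [])],
        fallback_group=payload.get("fallback_group", "Other_heterotroph"),
    )


@dataclass(frozen=True)
class TrophicAnnotation:
    asv_id: str
    trophic_mode: str
    functional_group: str
    genus: str  # rank-7 label, "NA" when unassigned


def classify_asv(asv_id: str, ranks: list[str], rules: RuleSet | None = None) -> TrophicAnnotation:
    """Classify one normalised 8-rank lineage.

    Deterministic: identical lineages always yield identical annotations.
    """
    if rules is None:
        rules = default_rules()
    if len(ranks) != N_RANKS:
        raise ValueError(
            f"lineage for {asv_id!r} has {len(ranks)} ranks after normalization, expected {N_RANKS}"
        )
    ranks = [r.strip() for r in ranks]
    mode, group = rules.match(ranks)
    genus = ranks[GENUS_RANK - 1] or "NA"
    return TrophicAnnotation(asv_id=asv_id, trophic_mode=mode, functional_group=group, genus=genus)


def annotate_dataset(ds: ASVDataset, rules: RuleSet | None = None) -> dict[str, TrophicAnnotation]:
    """Annotate every ASV in the dataset; total over ASVs."""
    if rules is None:
        rules = default_rules()
    return {
        asv: classify_asv(asv, ds.lineage_ranks(asv), rules) for asv in ds.asv_ids
    }


def group_sizes(annotations: dict[str, TrophicAnnotation]) -> dict[str, int]:
    """ASV count per functional group (summary logging aid)."""
    out: dict[str, int] = {}
    for ann in annotations.values():
        out[ann.functional_group] = out.get(ann.functional_group, 0) + 1
    return out
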