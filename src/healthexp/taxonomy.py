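"""SHA 2011 category taxonomies for healthcare functions (HC) and providers (HP).

The System of Health Accounts (SHA 2011) classifies health expenditure along two
axes used here: healthcare *functions* (what the money buys — curative care,
medical goods, prevention, ...) and healthcare *providers* (who delivers it —
hospitals, ambulatory providers, retailers, ...).  Each axis is a shallow forest:
level-1 aggregates, level-2 children (including a residual "not elsewhere
classified" — NEC — leaf that absorbs whatever fits the parent but no specific
child), and optionally level-3 detail.  Estimation elsewhere in this package is
carried out to the second hierarchical level; level-3 nodes are representable
for data storage but never modelled.

This module is the coordinate system for everything else: tree construction and
validation, enumeration of HC x HP cross-classification cells, exact hierarchical
aggregation, and re-coding of observations reported under the older SHA 2000
guidelines into the SHA 2011 framework.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from importlib import resources
from typing import Iterable, Mapping, Sequence

import pandas as pd

#: pseudo-code marking the margin ("total") position on an axis
TOTAL = "TOTAL"


class TaxonomyError(ValueError):
    """Raised when a category tree or mapping violates its invariants."""


@dataclass(frozen=True)
class CategoryNode:
    """A single SHA category.

    Parameters
    ----------
    code : str
        Category identifier, e.g. ``"HC1.1"`` or ``"HP3"``.
    axis : str
        ``"HC"`` or ``"HP"``.
    level : int
        Hierarchy level, 1-3.  Level-1 nodes have no parent.
    parent : str or None
        Code of the parent node (level ``level - 1``, same axis).
    label : str
        Human-readable name.
    is_nec : bool
        Whether this is a residual not-elsewhere-classified leaf.
    """

    code: str
    axis: str
    level: int
    parent: str | None = None
    label: str = ""
    is_nec: bool = False


class CategoryTree:
    """A validated forest of :class:`CategoryNode` on a single axis.

    Use :func:`build_tree` (or :meth:`from_json`) rather than constructing
    directly; the constructor assumes already-validated input.
    """

    def __init__(self, axis: str, nodes: Mapping[str, CategoryNode]):
        self.axis = axis
        self.nodes: dict[str, CategoryNode] = dict(nodes)
        self._children: dict[str, list[str]] = {c: [] for c in self.nodes}
        for node in self.nodes.values():
            if node.parent is not None:
                self._children[node.parent].append(node.code)
        for kids in self._children.values():
            kids.sort()

    def __len__(self) -> int:
        return len(self.nodes)

    def __contains__(self, code: str) -> bool:
        return code in self.nodes

    @property
    def codes(self) -> list[str]:
        return sorted(self.nodes)

    def level(self, k: int) -> list[str]:
        """Codes at hierarchy level ``k``, sorted."""
        return sorted(c for c, n in self.nodes.items() if n.level == k)

    def children(self, code: str) -> list[str]:
        if code not in self.nodes:
            raise TaxonomyError(f"unknown {self.axis} code {code!r}")
        return list(self._children[code])

    def parent(self, code: str) -> str | None:
        if code not in self.nodes:
            raise TaxonomyError(f"unknown {self.axis} code {code!r}")
        return self.nodes[code].parent

    def leaves(self, max_level: int = 2) -> list[str]:
        """Leaf codes of the modelled hierarchy.

        A leaf is a node at ``max_level`` or a shallower node with no children
        at or below ``max_level`` (a childless level-1 node stands in as its
        own single leaf).
        """
        out = []
        for code, node in self.nodes.items():
            if node.level > max_level:
                continue
            kids = [k for k in self._children[code] if self.nodes[k].level <= max_level]
            if node.level == max_level or not kids:
                out.append(code)
        return sorted(out)

    # ------------------------------------------------------------------ I/O
    def to_dict(self) -> dict:
        return {
            "axis": self.axis,
            "nodes": [
                {
                    "code": n.code,
                    "level": n.level,
                    "parent": n.parent,
                    "label": n.label,
                    "is_nec": n.is_nec,
                }
                for n in (self.nodes[c] for c in self.codes)
            ],
        }

    def to_json(self, path) -> None:
        with open(path, "w") as fh:
            json.dump(self.to_dict(), fh, indent=1)

    def to_csv(self, path) -> None:
        pd.DataFrame(self.to_dict()["nodes"]).to_csv(path, index=False)

    @classmethod
    def from_dict(cls, payload: Mapping) -> "CategoryTree":
        axis = payload["axis"]
        nodes = [
            CategoryNode(
                code=d["code"],
                axis=axis,
                level=int(d["level"]),
                parent=d.get("parent") or None,
                label=d.get("label", ""),
                is_nec=bool(d.get("is_nec", False)),
            )
            for d in payload["nodes"]
        ]
        return build_tree(nodes)

    @classmethod
    def from_json(cls, path) -> "CategoryTree":
        with open(path) as fh:
            return cls.from_dict(json.load(fh))

    @classmethod
    def from_yaml(cls, path) -> "CategoryTree":
        import yaml

        with open(path) as fh:
            return cls.from_dict(yaml.safe_load(fh))


def build_tree(nodes: Iterable[CategoryNode]) -> CategoryTree:
    """Validate a node list and assemble a :class:`CategoryTree`.

    Raises
    ------
    TaxonomyError
        On an empty list, mixed axes, duplicate codes, a parent reference to a
        missing code, or a level skip (e.g. a level-3 child of a level-1 node).
    """
    nodes = list(nodes)
    if not nodes:
        raise TaxonomyError("empty node list")
    axes = {n.axis for n in nodes}
    if len(axes) != 1:
        raise TaxonomyError(f"nodes span multiple axes: {sorted(axes)}")
    axis = axes.pop()
    by_code: dict[str, CategoryNode] = {}
    for n in nodes:
        if n.code in by_code:
            raise TaxonomyError(f"duplicate code {n.code!r}")
        if n.level not in (1, 2, 3):
            raise TaxonomyError(f"node {n.code!r} has invalid level {n.level}")
        by_code[n.code] = n
    for n in nodes:
        if n.level == 1:
            if n.parent is not None:
                raise TaxonomyError(f"level-1 node {n.code!r} must not have a parent")
            continue
        if n.parent is None:
            raise TaxonomyError(f"node {n.code!r} (level {n.level}) has no parent")
        if n.parent not in by_code:
            raise TaxonomyError(f"node {n.code!r} references missing parent {n.parent!r}")
        plevel = by_code[n.parent].level
        if plevel != n.level - 1:
            raise TaxonomyError(
                f"node {n.code!r} (level {n.level}) has parent {n.parent!r} "
                f"of level {plevel}; parent must be level {n.level - 1}"
            )
    return CategoryTree(axis, by_code)


def enumerate_cross_cells(hc: CategoryTree, hp: CategoryTree) -> list[tuple[str, str]]:
    """All (HC code, HP code) cross-classification pairs.

    With the default retained trees (41 HC x 21 HP nodes) this yields the 861
    cells of the most complete reported expenditure matrix.
    """
    return [(h, p) for h in hc.codes for p in hp.codes]


def aggregate_children(
    values: Mapping[str, float], tree: CategoryTree, parent: str
) -> float:
    """Exact sum of a parent's children values (e.g. per-capita expenditures).

    ``values`` must cover every child of ``parent``; hierarchical accounting
    admits no tolerance here — a missing child is an error, never an implicit
    zero.
    """
    kids = tree.children(parent)
    if not kids:
        raise TaxonomyError(f"{parent!r} has no children to aggregate")
    missing = [k for k in kids if k not in values]
    if missing:
        raise TaxonomyError(f"missing child values for {parent!r}: {missing}")
    return float(sum(values[k] for k in kids))


# --------------------------------------------------------------------------
# SHA 2000 -> SHA 2011 reconciliation
# --------------------------------------------------------------------------

RULE_KINDS = ("one_to_one", "many_to_one", "one_to_many_ambiguous")


@dataclass(frozen=True)
class ShaMappingRule:
    """Re-coding rule for one SHA 2000 source category.

    ``one_to_one`` and ``many_to_one`` rules re-code deterministically (several
    many_to_one sources may share a target, in which case their amounts are
    summed).  ``one_to_many_ambiguous`` rules mark SHA 2000 categories that
    were split across several SHA 2011 categories with an undefined
    proportioning; such observations are *dropped* and their targets left
    missing, to be estimated by the model rather than guessed.
    """

    source_code: str
    target_codes: tuple[str, ...]
    kind: str

    def __post_init__(self):
        if self.kind not in RULE_KINDS:
            raise TaxonomyError(f"unknown rule kind {self.kind!r}")
        if self.kind == "one_to_many_ambiguous" and len(self.target_codes) < 2:
            raise TaxonomyError(
                f"ambiguous rule for {self.source_code!r} needs >=2 targets"
            )
        if self.kind != "one_to_many_ambiguous" and len(self.target_codes) != 1:
            raise TaxonomyError(
                f"rule for {self.source_code!r} of kind {self.kind} needs exactly 1 target"
            )


def _rule_index(rules: Sequence[ShaMappingRule]) -> dict[str, ShaMappingRule]:
    idx: dict[str, ShaMappingRule] = {}
    for r in rules:
        if r.source_code in idx:
            raise TaxonomyError(f"source {r.source_code!r} appears in multiple rules")
        idx[r.source_code] = r
    return idx


def map_sha2000(obs: pd.DataFrame, rules: Sequence[ShaMappingRule]) -> pd.DataFrame:
    """Re-code SHA-2000-coded observation rows into the SHA 2011 framework.

    Rows already coded SHA 2011 pass through unchanged.  For SHA 2000 rows,
    each present code (HC and/or HP) is looked up: deterministic rules re-code
    (with many_to_one amounts summed within country-year and resulting cell),
    while a row touching any ambiguous rule is dropped — its SHA 2011 targets
    stay missing ("treated as missing values", to be model-estimated).

    Raises
    ------
    TaxonomyError
        If a SHA 2000 row carries a code with no rule.
    """
    idx = _rule_index(rules)
    old = obs[obs["sha_version"] == 2000]
    new = obs[obs["sha_version"] != 2000]
    if old.empty:
        return obs.copy()

    def _map_code(code):
        if pd.isna(code) or code is None:
            return code, False
        rule = idx.get(code)
        if rule is None:
            raise TaxonomyError(f"no SHA 2000 mapping rule for code {code!r}")
        if rule.kind == "one_to_many_ambiguous":
            return None, True
        return rule.target_codes[0], False

    mapped_rows = []
    for _, row in old.iterrows():
        hc, drop_hc = _map_code(row["hc_code"])
        hp, drop_hp = _map_code(row["hp_code"])
        if drop_hc or drop_hp:
            continue
        row = row.copy()
        row["hc_code"], row["hp_code"] = hc, hp
        row["sha_version"] = 2011
        mapped_rows.append(row)

    if mapped_rows:
        mapped = pd.DataFrame(mapped_rows)
        keys = [
            c
            for c in mapped.columns
            if c != "amount"
        ]
        mapped = (
            mapped.groupby(keys, dropna=False, as_index=False, sort=False)["amount"]
            .sum()
            .reindex(columns=obs.columns)
        )
    else:
        mapped = obs.iloc[0:0]
    out = pd.concat([new, mapped], ignore_index=True)
    return out


# --------------------------------------------------------------------------
# Default retained taxonomy (41 HC, 21 HP)
# --------------------------------------------------------------------------
# The retained category set keeps the most-reported SHA 2011 categories at
# hierarchy levels 1-2.  Functions follow the published level-1/level-2 layout
# (curative, rehabilitative, long-term, ancillary, medical goods, preventive,
# governance/administration, other), completed with standard SHA 2011 subcodes
# and NEC leaves; providers cover hospitals, residential long-term care,
# ambulatory care, ancillary services, retailers, preventive-care providers,
# administration, rest of economy and rest of world.  Both trees are
# config-overridable (JSON/YAML) if a different retained set is wanted.

_HC_SPEC: list[tuple[str, int, str | None, str]] = [
    ("HC1", 1, None, "Curative care"),
    ("HC1.1", 2, "HC1", "Curative care - inpatient"),
    ("HC1.2", 2, "HC1", "Curative care - day"),
    ("HC1.3", 2, "HC1", "Curative care - outpatient"),
    ("HC1.4", 2, "HC1", "Curative care - home-based"),
    ("HC1.nec", 2, "HC1", "Curative care - NEC"),
    ("HC2", 1, None, "Rehabilitative care"),
    ("HC2.1", 2, "HC2", "Rehabilitative care - inpatient"),
    ("HC2.2", 2, "HC2", "Rehabilitative care - day"),
    ("HC2.3", 2, "HC2", "Rehabilitative care - outpatient"),
    ("HC2.4", 2, "HC2", "Rehabilitative care - home-based"),
    ("HC2.nec", 2, "HC2", "Rehabilitative care - NEC"),
    ("HC3", 1, None, "Long-term care"),
    ("HC3.1", 2, "HC3", "Long-term care - inpatient"),
    ("HC3.2", 2, "HC3", "Long-term care - day"),
    ("HC3.3", 2, "HC3", "Long-term care - outpatient"),
    ("HC3.4", 2, "HC3", "Long-term care - home-based"),
    ("HC3.nec", 2, "HC3", "Long-term care - NEC"),
    ("HC4", 1, None, "Ancillary services"),
    ("HC4.1", 2, "HC4", "Laboratory services"),
    ("HC4.2", 2, "HC4", "Imaging services"),
    ("HC4.3", 2, "HC4", "Patient transportation"),
    ("HC4.nec", 2, "HC4", "Ancillary services - NEC"),
    ("HC5", 1, None, "Medical goods"),
    ("HC5.1", 2, "HC5", "Pharmaceuticals and other medical non-durable goods"),
    ("HC5.2", 2, "HC5", "Therapeutic appliances and prosthetics"),
    ("HC5.nec", 2, "HC5", "Medical goods - NEC"),
    ("HC6", 1, None, "Preventive care"),
    ("HC6.1", 2, "HC6", "IEC programmes"),
    ("HC6.2", 2, "HC6", "Immunisation programmes"),
    ("HC6.3", 2, "HC6", "Early disease detection programmes"),
    ("HC6.4", 2, "HC6", "Healthy condition monitoring programmes"),
    ("HC6.5", 2, "HC6", "Epidemiological surveillance and risk and disease control"),
    ("HC6.6", 2, "HC6", "Preparing for disaster and emergency response"),
    ("HC6.nec", 2, "HC6", "Preventive care - NEC"),
    ("HC7", 1, None, "Governance and health system administration"),
    ("HC7.1", 2, "HC7", "Governance and health system administration"),
    ("HC7.2", 2, "HC7", "Administration of health financing"),
    ("HC7.nec", 2, "HC7", "Governance and administration - NEC"),
    ("HC9", 1, None, "Other healthcare services"),
    ("HC9.nec", 2, "HC9", "Other healthcare services - NEC"),
]

_HP_SPEC: list[tuple[str, int, str | None, str]] = [
    ("HP1", 1, None, "Hospitals"),
    ("HP1.1", 2, "HP1", "General hospitals"),
    ("HP1.2", 2, "HP1", "Mental health hospitals"),
    ("HP1.3", 2, "HP1", "Specialised hospitals"),
    ("HP1.nec", 2, "HP1", "Hospitals - NEC"),
    ("HP2", 1, None, "Residential long-term care facilities"),
    ("HP3", 1, None, "Providers of ambulatory health care"),
    ("HP3.1", 2, "HP3", "Medical practices"),
    ("HP3.2", 2, "HP3", "Dental practices"),
    ("HP3.3", 2, "HP3", "Other health care practitioners"),
    ("HP3.4", 2, "HP3", "Ambulatory health care centres"),
    ("HP3.5", 2, "HP3", "Providers of home health care services"),
    ("HP3.nec", 2, "HP3", "Ambulatory health care - NEC"),
    ("HP4", 1, None, "Providers of ancillary services"),
    ("HP5", 1, None, "Retailers and other providers of medical goods"),
    ("HP5.1", 2, "HP5", "Pharmacies"),
    ("HP5.nec", 2, "HP5", "Retailers of medical goods - NEC"),
    ("HP6", 1, None, "Providers of preventive care"),
    ("HP7", 1, None, "Providers of health system administration and financing"),
    ("HP8", 1, None, "Rest of economy"),
    ("HP9", 1, None, "Rest of world"),
]


def _spec_to_nodes(spec, axis):
    return [
        CategoryNode(code=c, axis=axis, level=lv, parent=p, label=lab,
                     is_nec=c.endswith(".nec"))
        for c, lv, p, lab in spec
    ]


def default_hc_tree() -> CategoryTree:
    """The default retained HC (functions) tree: 41 nodes, levels 1-2."""
    return build_tree(_spec_to_nodes(_HC_SPEC, "HC"))


def default_hp_tree() -> CategoryTree:
    """The default retained HP (providers) tree: 21 nodes, levels 1-2."""
    return build_tree(_spec_to_nodes(_HP_SPEC, "HP"))


def default_mapping_rules(
    hc: CategoryTree | None = None, hp: CategoryTree | None = None
) -> list[ShaMappingRule]:
    """Default SHA 2000 -> SHA 2011 re-coding rules.

    Most categories are unchanged between the two guideline revisions
    (identity rules).  The preventive-care block changed materially: the
    SHA 2000 "prevention of communicable diseases" category was split across
    SHA 2011 immunisation and surveillance programmes with undefined
    proportions (ambiguous -> dropped as missing), while maternal/child and
    school health programmes both fold into SHA 2011 healthy-condition
    monitoring (many_to_one).  The rule table is configuration, not code;
    ship your own JSON to replace it.
    """
    hc = hc or default_hc_tree()
    hp = hp or default_hp_tree()
    special: dict[str, ShaMappingRule] = {
        "HC6.1": ShaMappingRule("HC6.1", ("HC6.4",), "many_to_one"),
        "HC6.2": ShaMappingRule("HC6.2", ("HC6.4",), "many_to_one"),
        "HC6.3": ShaMappingRule("HC6.3", ("HC6.2", "HC6.5"), "one_to_many_ambiguous"),
    }
    rules = list(special.values())
    for code in hc.codes + hp.codes:
        if code not in special and code not in ("HC6.4", "HC6.5"):
            rules.append(ShaMappingRule(code, (code,), "one_to_one"))
    return rules


def mapping_rules_to_json(rules: Sequence[ShaMappingRule], path) -> None:
    with open(path, "w") as fh:
        json.dump(
            [
                {"source_code": r.source_code, "target_codes": list(r.target_codes),
                 "kind": r.kind}
                for r in rules
            ],
            fh,
            indent=1,
        )


def mapping_rules_from_json(path) -> list[ShaMappingRule]:
    with open(path) as fh:
        payload = json.load(fh)
    return [
        ShaMappingRule(d["source_code"], tuple(d["target_codes"]), d["kind"])
        for d in payload
    ]


def load_table1_fixture() -> pd.DataFrame:
    """Published global per-capita expenditures (2017 US$) by HC category.

    Columns: ``code, label, level, mean, lower, upper`` — the level-1 rows are
    exact integer sums of their level-2 children, which makes this table the
    worked example for :func:`aggregate_children`.
    """
    with resources.files("healthexp.data").joinpath("table1_global_2017.csv").open() as fh:
        return pd.read_csv(fh)


# --------------------------------------------------------------------------
# Modelling layout
# --------------------------------------------------------------------------


@dataclass
class Layout:
    """Index arrays tying the two trees to the modelled quantity set.

    The modelled quantities are: level-1 totals on each axis, leaf totals
    (level-2 nodes, with a childless level-1 node standing in as its own
    leaf), the level-1 x level-1 cross matrix, and the leaf x leaf cross
    matrix.  Everything else (level-1 margins of the cross table, mixed-level
    cross cells) is derived by aggregation.
    """

    hc: CategoryTree
    hp: CategoryTree
    hc_l1: list[str] = field(init=False)
    hp_l1: list[str] = field(init=False)
    hc_leaf: list[str] = field(init=False)
    hp_leaf: list[str] = field(init=False)
    hc_leaf_parent: list[int] = field(init=False)
    hp_leaf_parent: list[int] = field(init=False)

    def __post_init__(self):
        self.hc_l1 = self.hc.level(1)
        self.hp_l1 = self.hp.level(1)
        self.hc_leaf = self.hc.leaves()
        self.hp_leaf = self.hp.leaves()
        self.hc_leaf_parent = [
            self.hc_l1.index(self.hc.parent(c) or c) for c in self.hc_leaf
        ]
        self.hp_leaf_parent = [
            self.hp_l1.index(self.hp.parent(c) or c) for c in self.hp_leaf
        ]

    def hc_children_of(self, l1_code: str) -> list[int]:
        """Leaf indices under one level-1 HC node."""
        j = self.hc_l1.index(l1_code)
        return [i for i, p in enumerate(self.hc_leaf_parent) if p == j]

    def hp_children_of(self, l1_code: str) -> list[int]:
        j = self.hp_l1.index(l1_code)
        return [i for i, p in enumerate(self.hp_leaf_parent) if p == j]
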