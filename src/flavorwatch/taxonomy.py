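"""Hierarchical e-liquid flavor taxonomy: loading, validation, and term classification.

E-liquid flavors are organised in a three-level hierarchy: seven major
categories (fruit, sweets, beverage, tobacco, menthol_or_mint, mixed,
others), subcategories within each (e.g. fruit -> berry, tropical, citrus,
melon, mixed_fruit, others), and specific flavor keywords at the leaves.
Two categories play a structural role and must always exist: ``mixed``
receives flavors whose ingredients span two or more categories, and
``others`` receives anything that cannot be resolved at all.

The taxonomy ships as a diff-able delimited text file (one row per keyword,
with optional alias and ingredient columns); a fixture reproducing the seven
printed categories is bundled as package data.
"""

from __future__ import annotations

import re
from dataclasses import dataclass, field
from importlib import resources
from pathlib import Path
from typing import Iterable, Iterator, Mapping, NamedTuple

__all__ = [
    "TaxonomyError",
    "TaxonomyPath",
    "FlavorTerm",
    "CategoryNode",
    "FlavorTaxonomy",
    "load_taxonomy",
    "bundled_taxonomy",
    "classify_term",
    "normalize_keyword",
]

#: Category names of the bundled classification, in canonical order.
CATEGORIES = (
    "fruit",
    "sweets",
    "beverage",
    "tobacco",
    "menthol_or_mint",
    "mixed",
    "others",
)

#: Categories that every valid taxonomy must contain (fallback targets).
REQUIRED_CATEGORIES = ("mixed", "others")


class TaxonomyError(ValueError):
    """Raised when a taxonomy configuration violates a structural invariant."""


class TaxonomyPath(NamedTuple):
    """Resolved position of a flavor term: (category, subcategory, keyword)."""

    category: str
    subcategory: str
    keyword: str


def normalize_keyword(text: str) -> str:
    """Lower-case and collapse internal whitespace of a flavor keyword."""
    return re.sub(r"\s+", " ", text.strip().lower())


@dataclass(frozen=True)
class FlavorTerm:
    """A flavor name as written, plus its standardized form.

    ``standardized`` is non-empty exactly when the surface form resolved
    against the taxonomy keywords or the alias table.
    ``ingredient_categories`` is the set of flavor categories implied by the
    term's configured ingredients (empty when none are configured).
    """

    surface: str
    standardized: str = ""
    ingredient_categories: frozenset[str] = frozenset()


@dataclass(frozen=True)
class CategoryNode:
    """One major flavor category with its (subcategory, keywords) groups."""

    name: str
    subcategories: tuple[tuple[str, tuple[str, ...]], ...]


@dataclass
class FlavorTaxonomy:
    """Validated three-level flavor classification.

    Construction is normally done through :func:`load_taxonomy`; the
    constructor validates the structural invariants (required fallback
    categories, keyword uniqueness across paths, non-empty levels).
    """

    categories: tuple[CategoryNode, ...]
    aliases: Mapping[str, str] = field(default_factory=dict)
    ingredients: Mapping[str, frozenset[str]] = field(default_factory=dict)
    version: str = ""

    def __post_init__(self) -> None:
        if not self.categories:
            raise TaxonomyError("taxonomy has no categories")
        self._paths: dict[str, TaxonomyPath] = {}
        names = [c.name for c in self.categories]
        if len(set(names)) != len(names):
            raise TaxonomyError("duplicate category names in taxonomy")
        for required in REQUIRED_CATEGORIES:
            if required not in names:
                raise TaxonomyError(
                    f"taxonomy must contain a {required!r} category (fallback target)"
                )
        for cat in self.categories:
            if not cat.subcategories:
                raise TaxonomyError(f"category {cat.name!r} has no subcategories")
            sub_names = [s for s, _ in cat.subcategories]
            if len(set(sub_names)) != len(sub_names):
                raise TaxonomyError(
                    f"duplicate subcategory labels under category {cat.name!r}"
                )
            for sub, keywords in cat.subcategories:
                if not keywords:
                    raise TaxonomyError(
                        f"subcategory {cat.name}/{sub} has no keywords"
                    )
                for kw in keywords:
                    if kw != normalize_keyword(kw):
                        raise TaxonomyError(
                            f"keyword {kw!r} is not lower-cased/whitespace-normalized"
                        )
                    path = TaxonomyPath(cat.name, sub, kw)
                    if kw in self._paths:
                        other = self._paths[kw]
                        raise TaxonomyError(
                            f"keyword {kw!r} appears under two paths: "
                            f"{other.category}/{other.subcategory} and "
                            f"{path.category}/{path.subcategory}"
                        )
                    self._paths[kw] = path
        for alias, target in self.aliases.items():
            if target not in self._paths:
                raise TaxonomyError(
                    f"alias {alias!r} points to unknown keyword {target!r}"
                )
            if alias in self._paths:
                raise TaxonomyError(
                    f"alias {alias!r} collides with a taxonomy keyword"
                )

    # -- queries ---------------------------------------------------------

    @property
    def category_names(self) -> tuple[str, ...]:
        return tuple(c.name for c in self.categories)

    def keywords(self) -> tuple[str, ...]:
        """All canonical keywords, in taxonomy order."""
        return tuple(self._paths)

    def match_terms(self) -> dict[str, str]:
        """Surface form -> canonical keyword for every matchable string."""
        terms = {kw: kw for kw in self._paths}
        terms.update(self.aliases)
        return terms

    def path_of(self, keyword: str) -> TaxonomyPath:
        """Taxonomy path of a canonical keyword (KeyError if absent)."""
        return self._paths[keyword]

    def __contains__(self, keyword: str) -> bool:
        return keyword in self._paths

    def subcategories_of(self, category: str) -> tuple[str, ...]:
        for cat in self.categories:
            if cat.name == category:
                return tuple(s for s, _ in cat.subcategories)
        raise KeyError(category)

    def keywords_of(self, category: str, subcategory: str | None = None) -> tuple[str, ...]:
        for cat in self.categories:
            if cat.name == category:
                return tuple(
                    kw
                    for sub, kws in cat.subcategories
                    if subcategory is None or sub == subcategory
                    for kw in kws
                )
        raise KeyError(category)

    def standardize(self, surface: str) -> FlavorTerm:
        """Resolve a raw flavor name to its canonical form.

        Alias resolution is applied after whitespace/case normalization.
        Terms absent from both the keyword and alias tables come back with an
        empty ``standardized`` field.
        """
        norm = normalize_keyword(surface)
        std = self.aliases.get(norm, norm if norm in self._paths else "")
        ingredients = self.ingredients.get(std, frozenset())
        return FlavorTerm(surface=surface, standardized=std, ingredient_categories=ingredients)

    def with_keyword(
        self,
        category: str,
        subcategory: str,
        keyword: str,
        ingredients: Iterable[str] = (),
    ) -> "FlavorTaxonomy":
        """Return a new taxonomy with one extra keyword (fixture stays untouched)."""
        keyword = normalize_keyword(keyword)
        cats = []
        for cat in self.categories:
            if cat.name != category:
                cats.append(cat)
                continue
            subs = []
            placed = False
            for sub, kws in cat.subcategories:
                if sub == subcategory:
                    subs.append((sub, kws + (keyword,)))
                    placed = True
                else:
                    subs.append((sub, kws))
            if not placed:
                subs.append((subcategory, (keyword,)))
            cats.append(CategoryNode(cat.name, tuple(subs)))
        if category not in self.category_names:
            cats.append(CategoryNode(category, ((subcategory, (keyword,)),)))
        new_ingredients = dict(self.ingredients)
        if ingredients:
            new_ingredients[keyword] = frozenset(ingredients)
        return FlavorTaxonomy(
            categories=tuple(cats),
            aliases=dict(self.aliases),
            ingredients=new_ingredients,
            version=self.version,
        )


def _parse_rows(lines: Iterator[str], source: str) -> FlavorTaxonomy:
    header: list[str] | None = None
    by_category: dict[str, dict[str, list[str]]] = {}
    aliases: dict[str, str] = {}
    ingredients: dict[str, frozenset[str]] = {}
    n_rows = 0
    for lineno, raw in enumerate(lines, start=1):
        line = raw.rstrip("\n")
        if not line.strip() or line.lstrip().startswith("#"):
            continue
        fields = line.split("\t")
        if header is None:
            header = [f.strip().lower() for f in fields]
            expected = ["category", "subcategory", "keyword"]
            if header[: len(expected)] != expected:
                raise TaxonomyError(
                    f"{source}:{lineno}: header must start with "
                    "'category<TAB>subcategory<TAB>keyword'"
                )
            continue
        fields += [""] * (5 - len(fields))
        category, subcategory, keyword, alias_field, ingredient_field = (
            f.strip() for f in fields[:5]
        )
        if not (category and subcategory and keyword):
            raise TaxonomyError(f"{source}:{lineno}: incomplete row: {line!r}")
        keyword = normalize_keyword(keyword)
        by_category.setdefault(category, {}).setdefault(subcategory, []).append(keyword)
        for alias in filter(None, (a.strip() for a in alias_field.split(";"))):
            aliases[normalize_keyword(alias)] = keyword
        ing = frozenset(
            filter(None, (i.strip().lower() for i in ingredient_field.split(";")))
        )
        if ing:
            ingredients[keyword] = ing
        n_rows += 1
    if n_rows == 0:
        raise TaxonomyError(f"{source}: no taxonomy rows found")
    categories = tuple(
        CategoryNode(
            name,
            tuple((sub, tuple(kws)) for sub, kws in subs.items()),
        )
        for name, subs in by_category.items()
    )
    return FlavorTaxonomy(
        categories=categories, aliases=aliases, ingredients=ingredients, version=source
    )


def load_taxonomy(path: str | Path) -> FlavorTaxonomy:
    """Load and validate a taxonomy config file.

    Any structural violation (duplicate keyword across paths, missing
    mixed/others category, empty levels, empty file) raises
    :class:`TaxonomyError`; invalid configs are never returned.
    """
    path = Path(path)
    with path.open(encoding="utf-8") as fh:
        return _parse_rows(iter(fh), source=path.name)


def bundled_taxonomy() -> FlavorTaxonomy:
    """The packaged seven-category flavor classification fixture."""
    text = (
        resources.files("flavorwatch.data")
        .joinpath("table1_taxonomy.tsv")
        .read_text(encoding="utf-8")
    )
    return _parse_rows(iter(text.splitlines()), source="table1_taxonomy.tsv")


def classify_term(term: FlavorTerm | str, tax: FlavorTaxonomy) -> TaxonomyPath:
    """Classify one flavor term into its (category, subcategory, keyword) path.

    Total and deterministic: a term whose standardized keyword is in the
    taxonomy gets that keyword's path; a term whose configured ingredients
    span two or more distinct non-``others`` categories goes to
    (mixed, mixed, term); a term with exactly one implied category goes to
    that category's ``others`` subcategory; anything unresolvable goes to
    (others, others, term).
    """
    if isinstance(term, str):
        term = tax.standardize(term)
    if term.standardized and term.standardized in tax:
        return tax.path_of(term.standardized)
    name = term.standardized or normalize_keyword(term.surface)
    implied = {c for c in term.ingredient_categories if c != "others"}
    implied &= set(tax.category_names)
    if len(implied) >= 2:
        return TaxonomyPath("mixed", "mixed", name)
    if len(implied) == 1:
        category = implied.pop()
        subs = tax.subcategories_of(category)
        sub = "others" if "others" in subs else subs[0]
        return TaxonomyPath(category, sub, name)
    return TaxonomyPath("others", "others", name)
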