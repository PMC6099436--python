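"""Biotransformation rules and suspect-candidate generation.

Plants transform xenobiotics much like mammalian liver does: phase-I
hydroxylation (+O) and N-demethylation (net -CH2), plus phase-II
conjugation — here amide coupling with free amino acids, a net addition of
the amino acid minus water. Applying such rules combinatorially to a parent
drug yields the suspect list that exact-mass screening consumes; an
explicit literature suspect list can be loaded instead (or in addition).
"""

from __future__ import annotations

from collections import deque
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import pandas as pd

from .chem import MolecularFormula, apply_delta, parse_formula, protonated_mz

__all__ = [
    "TransformationRule",
    "Candidate",
    "AMINO_ACID_FORMULAS",
    "PARENT_DRUGS",
    "builtin_rules",
    "enumerate_candidates",
    "load_suspect_list",
    "reconstructed_suspect_list",
]

#: Free (neutral) proteinogenic amino acids; conjugation subtracts one H2O.
AMINO_ACID_FORMULAS: Mapping[str, str] = {
    "Gly": "C2H5NO2", "Ala": "C3H7NO2", "Ser": "C3H7NO3", "Pro": "C5H9NO2",
    "Val": "C5H11NO2", "Thr": "C4H9NO3", "Cys": "C3H7NO2S", "Leu": "C6H13NO2",
    "Ile": "C6H13NO2", "Asn": "C4H8N2O3", "Asp": "C4H7NO4", "Gln": "C5H10N2O3",
    "Lys": "C6H14N2O2", "Glu": "C5H9NO4", "Met": "C5H11NO2S", "His": "C6H9N3O2",
    "Phe": "C9H11NO2", "Arg": "C6H14N4O2", "Tyr": "C9H11NO3", "Trp": "C11H12N2O2",
}

#: The three administered antidepressants (name -> neutral sum formula).
PARENT_DRUGS: Mapping[str, str] = {
    "STR": "C17H17Cl2N",     # sertraline
    "CLP": "C19H23ClN2",     # clomipramine
    "TZN": "C19H22ClN5O",    # trazodone
}

_H2O = parse_formula("H2O").as_dict()


@dataclass(frozen=True)
class TransformationRule:
    """A single biotransformation step.

    Either a ``delta`` rule (signed element-count change, e.g. +O for
    hydroxylation) or a ``product`` rule that replaces the whole formula
    (ring-system cleavages that no element delta can express). ``requires``
    restricts a product rule to one substrate; ``max_applications`` caps
    how often the rule may occur in one chain (None = bounded only by the
    enumeration depth). ``prefix``/``suffix`` build human-readable labels.
    """

    name: str
    delta: Mapping[str, int] | None = None
    product: MolecularFormula | None = None
    requires: MolecularFormula | None = None
    max_applications: int | None = None
    prefix: str = ""
    suffix: str = ""
    product_name: str = ""

    def __post_init__(self):
        if (self.delta is None) == (self.product is None):
            raise ValueError(f"rule {self.name!r}: exactly one of delta/product")

    def apply(self, f: MolecularFormula) -> MolecularFormula | None:
        """Resulting formula, or None when the rule does not apply."""
        if self.product is not None:
            if self.requires is not None and f != self.requires:
                return None
            return self.product
        try:
            return apply_delta(f, self.delta)
        except ValueError:
            return None


@dataclass(frozen=True)
class Candidate:
    """A suspect species: parent drug plus an applied transformation chain.

    ``chains`` holds every distinct rule ordering that reaches this
    formula (provenance); ``chain`` is the canonical (first, shortest)
    one. The empty chain denotes the parent drug itself.
    """

    parent: str
    formula: MolecularFormula
    chains: tuple[tuple[str, ...], ...]
    source: str = "enumerated"
    name: str = ""
    expected_rt: float | None = None

    @property
    def chain(self) -> tuple[str, ...]:
        return self.chains[0] if self.chains else ()

    @property
    def is_parent(self) -> bool:
        return self.chain == ()

    @property
    def theoretical_mz(self) -> float:
        return protonated_mz(self.formula)

    def __str__(self) -> str:  # pragma: no cover - convenience
        return f"{self.name or self.parent} [{self.formula.hill()}]"


def builtin_rules(amino_acids: Sequence[str] = ("Phe", "Tyr")) -> tuple[TransformationRule, ...]:
    """Default rule set: hydroxylation, N-demethylation, amino-acid amide
    conjugation (condensation, -H2O) for the given amino acids, and the
    trazodone -> mCPP piperazine-ring cleavage (a product rule, since the
    loss of the triazolopyridinone moiety is not a simple delta)."""
    rules = [
        TransformationRule("hydroxylation", delta={"O": +1}, prefix="OH-"),
        TransformationRule("demethylation", delta={"C": -1, "H": -2}, prefix="DM-"),
    ]
    for aa in amino_acids:
        if aa not in AMINO_ACID_FORMULAS:
            raise ValueError(f"unknown amino acid {aa!r}")
        delta = parse_formula(AMINO_ACID_FORMULAS[aa]).as_dict()
        for el, n in _H2O.items():
            delta[el] = delta.get(el, 0) - n
        rules.append(
            TransformationRule(
                f"{aa}-conjugation", delta=delta, suffix=f" + {aa}",
                max_applications=1,
            )
        )
    rules.append(
        TransformationRule(
            "mCPP-cleavage",
            product=parse_formula("C10H13ClN2"),
            requires=parse_formula(PARENT_DRUGS["TZN"]),
            max_applications=1,
            product_name="mCPP",
        )
    )
    return tuple(rules)


def _label(parent: str, chain: tuple[str, ...],
           rules: Mapping[str, TransformationRule]) -> str:
    name = parent
    for rule_name in chain:
        r = rules[rule_name]
        if r.product is not None:
            name = r.product_name or r.name
        else:
            name = f"{r.prefix}{name}{r.suffix}"
    return name


def enumerate_candidates(
    parent: str,
    rules: Iterable[TransformationRule],
    max_depth: int = 2,
    parent_formula: MolecularFormula | str | None = None,
) -> list[Candidate]:
    """Breadth-first application of ``rules`` to a parent drug.

    Every chain of up to ``max_depth`` rule applications is explored;
    chains reaching an identical formula are collapsed into one candidate
    that retains all distinct chains as provenance. Rule applications
    producing negative element counts are silently skipped. Output is
    deterministic: sorted by theoretical m/z, then canonical chain; the
    candidate set at depth d is a superset of the set at depth d-1.
    """
    if max_depth < 0:
        raise ValueError("max_depth must be >= 0")
    if parent_formula is None:
        parent_formula = PARENT_DRUGS.get(parent)
        if parent_formula is None:
            raise ValueError(f"unknown parent drug {parent!r}; give parent_formula")
    if isinstance(parent_formula, str):
        parent_formula = parse_formula(parent_formula)
    rule_map = {r.name: r for r in sorted(rules, key=lambda r: r.name)}

    # formula -> set of chains reaching it
    reached: dict[MolecularFormula, set[tuple[str, ...]]] = {parent_formula: {()}}
    frontier: deque[tuple[MolecularFormula, tuple[str, ...]]] = deque([(parent_formula, ())])
    while frontier:
        f, chain = frontier.popleft()
        if len(chain) >= max_depth:
            continue
        for rule in rule_map.values():
            if (rule.max_applications is not None
                    and chain.count(rule.name) >= rule.max_applications):
                continue
            out = rule.apply(f)
            if out is None:
                continue
            new_chain = chain + (rule.name,)
            chains = reached.setdefault(out, set())
            if new_chain not in chains:
                chains.add(new_chain)
                frontier.append((out, new_chain))

    candidates = []
    for formula, chains in reached.items():
        ordered = tuple(sorted(chains, key=lambda c: (len(c), c)))
        candidates.append(
            Candidate(
                parent=parent,
                formula=formula,
                chains=ordered,
                source="enumerated",
                name=_label(parent, ordered[0], rule_map),
            )
        )
    candidates.sort(key=lambda c: (c.theoretical_mz, c.chain))
    return candidates


def reconstructed_suspect_list() -> list[Candidate]:
    """The literature-style suspect list shipped with the package.

    A *synthetic reconstruction* of the kind of candidate list a
    literature survey of human/animal metabolism of these three parents
    yields (hydroxylated, demethylated, oxidized and conjugated
    derivatives, 21 entries) — not any published supplementary table. Use
    it as a realistic default for list-based screening or as a template
    for your own CSV.
    """
    from importlib import resources

    ref = resources.files("phytoscreen").joinpath(
        "data/suspects_reconstructed_synthetic.csv")
    with resources.as_file(ref) as path:
        return load_suspect_list(path)


def load_suspect_list(path: str | Path) -> list[Candidate]:
    """Load an explicit suspect list from CSV.

    Expected columns: ``name``, ``formula``; optional ``parent`` and
    ``expected_rt_min``. Unparseable formulas raise ``ValueError`` naming
    the offending row (1-based, excluding the header).
    """
    path = Path(path)
    try:
        df = pd.read_csv(path)
    except pd.errors.EmptyDataError:
        return []
    if df.empty:
        return []
    missing = {"name", "formula"} - set(df.columns)
    if missing:
        raise ValueError(f"suspect list {path} lacks columns: {sorted(missing)}")
    out: list[Candidate] = []
    for i, row in enumerate(df.itertuples(index=False), start=1):
        try:
            formula = parse_formula(str(row.formula))
        except ValueError as exc:
            raise ValueError(f"suspect list {path}, row {i}: {exc}") from exc
        rt = getattr(row, "expected_rt_min", None)
        rt = None if rt is None or pd.isna(rt) else float(rt)
        parent = getattr(row, "parent", None)
        parent = str(row.name) if parent is None or pd.isna(parent) else str(parent)
        out.append(
            Candidate(
                parent=parent,
                formula=formula,
                chains=((),),
                source="suspect_list",
                name=str(row.name),
                expected_rt=rt,
            )
        )
    return out
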