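"""Single-seed-descent plant identifiers and pedigrees.

A cohort descends from one founder plant ``T``. Every descendant is named by
appending one seed index per generation and a greenhouse suffix, e.g.
``T.3.3.1.1_G1`` is the generation-4 plant reached by taking seed 3, then 3,
then 1, then 1, grown in greenhouse 1. The parent of any plant is obtained by
dropping the last path element, so the naming scheme *is* the pedigree.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Iterator

import numpy as np

__all__ = [
    "PlantID",
    "PlantIDError",
    "FOUNDER",
    "parse_plant_id",
    "Pedigree",
    "BranchPlan",
    "generate_pedigree",
]


class PlantIDError(ValueError):
    """Raised when a plant label cannot be parsed or is inconsistent."""


@dataclass(frozen=True, order=True)
class PlantID:
    """Identifier of one plant in a single-seed-descent lineage.

    Parameters
    ----------
    path:
        One positive seed index per generation of descent. The founder has an
        empty path.
    greenhouse:
        ``"G1"`` or ``"G2"`` for descendants; ``None`` for the founder.
    """

    path: tuple[int, ...]
    greenhouse: str | None = None

    def __post_init__(self) -> None:
        if any((not isinstance(d, (int, np.integer))) or d < 1 for d in self.path):
            raise PlantIDError(f"path elements must be positive integers: {self.path}")
        object.__setattr__(self, "path", tuple(int(d) for d in self.path))
        if self.path and self.greenhouse is None:
            raise PlantIDError("non-founder plants need a greenhouse suffix")
        if self.greenhouse is not None and not (
            self.greenhouse.startswith("G") and self.greenhouse[1:].isdigit()
        ):
            raise PlantIDError(f"bad greenhouse {self.greenhouse!r}")

    @property
    def generation(self) -> int:
        return len(self.path)

    @property
    def is_founder(self) -> bool:
        return not self.path

    @property
    def label(self) -> str:
        base = "T" + "".join(f".{d}" for d in self.path)
        if self.greenhouse is None:
            return base
        return f"{base}_{self.greenhouse}"

    def parent(self) -> "PlantID | None":
        """The plant one generation up, or ``None`` for the founder."""
        if self.is_founder:
            return None
        if self.generation == 1:
            return FOUNDER
        return PlantID(self.path[:-1], self.greenhouse)

    def is_ancestor_of(self, other: "PlantID") -> bool:
        """True when *other* descends from this plant (strict)."""
        if self.is_founder:
            return not other.is_founder
        return (
            other.greenhouse == self.greenhouse
            and other.generation > self.generation
            and other.path[: self.generation] == self.path
        )

    def child(self, index: int) -> "PlantID":
        if self.is_founder:
            raise PlantIDError("founder children need an explicit greenhouse")
        return PlantID(self.path + (index,), self.greenhouse)

    def __str__(self) -> str:  # pragma: no cover - convenience
        return self.label


FOUNDER = PlantID(())


def parse_plant_id(label: str) -> PlantID:
    """Parse a canonical label like ``"T.3.3.1.1.1.1.11_G1"``.

    The founder is written plain ``"T"``. Any malformed label raises
    :class:`PlantIDError` reporting the character position where parsing
    failed.
    """
    if not isinstance(label, str):
        raise PlantIDError(f"label must be a string, got {type(label).__name__}")
    if label == "T":
        return FOUNDER
    if not label.startswith("T."):
        raise PlantIDError(f"{label!r}: expected 'T.' at position 0")
    i = 1
    path: list[int] = []
    n = len(label)
    while i < n and label[i] == ".":
        i += 1
        j = i
        while j < n and label[j].isdigit():
            j += 1
        if j == i:
            raise PlantIDError(f"{label!r}: expected digits at position {i}")
        path.append(int(label[i:j]))
        i = j
    if i >= n or label[i] != "_":
        raise PlantIDError(f"{label!r}: expected '_G<k>' suffix at position {i}")
    suffix = label[i + 1 :]
    if not (suffix.startswith("G") and suffix[1:].isdigit()):
        raise PlantIDError(f"{label!r}: bad greenhouse suffix at position {i + 1}")
    return PlantID(tuple(path), suffix)


class Pedigree:
    """A forest of single-seed-descent lineages below one founder.

    The founder itself is not a member; every generation-1 plant has the
    founder as implicit parent, and every deeper plant's parent (label minus
    the last path element) must be present.
    """

    def __init__(self, plants: Iterable[PlantID]):
        self._plants: dict[str, PlantID] = {}
        for p in plants:
            if p.is_founder:
                continue
            self._plants[p.label] = p
        self._children: dict[str, list[PlantID]] = {}
        for p in self._plants.values():
            par = p.parent()
            assert par is not None
            if p.generation > 1 and par.label not in self._plants:
                raise PlantIDError(f"parent {par.label} of {p.label} missing from pedigree")
            self._children.setdefault(par.label, []).append(p)
        for kids in self._children.values():
            kids.sort()

    def __len__(self) -> int:
        return len(self._plants)

    def __iter__(self) -> Iterator[PlantID]:
        return iter(self.plants)

    def __contains__(self, item: object) -> bool:
        if isinstance(item, PlantID):
            return item.label in self._plants
        return item in self._plants

    @property
    def founder(self) -> PlantID:
        return FOUNDER

    @property
    def plants(self) -> list[PlantID]:
        return sorted(self._plants.values(), key=lambda p: (p.generation, p.label))

    @property
    def labels(self) -> list[str]:
        return [p.label for p in self.plants]

    def get(self, label: str) -> PlantID:
        try:
            return self._plants[label]
        except KeyError:
            raise KeyError(f"plant {label!r} not in pedigree") from None

    def parent(self, plant: PlantID | str) -> PlantID:
        p = self.get(plant) if isinstance(plant, str) else plant
        par = p.parent()
        if par is None:
            raise PlantIDError("the founder has no parent")
        return par

    def children(self, plant: PlantID | str) -> list[PlantID]:
        label = plant if isinstance(plant, str) else plant.label
        return list(self._children.get(label, []))

    def descendants(self, plant: PlantID | str) -> set[PlantID]:
        """All strict descendants of *plant* present in the pedigree."""
        label = plant if isinstance(plant, str) else plant.label
        out: set[PlantID] = set()
        stack = list(self._children.get(label, []))
        while stack:
            p = stack.pop()
            out.add(p)
            stack.extend(self._children.get(p.label, []))
        return out

    def ancestors(self, plant: PlantID | str) -> list[PlantID]:
        """Parent chain from the plant up to (excluding) the founder."""
        p = self.get(plant) if isinstance(plant, str) else plant
        chain: list[PlantID] = []
        while p.generation > 1:
            p = p.parent()  # type: ignore[assignment]
            chain.append(p)
        return chain

    def by_generation(self, g: int) -> list[PlantID]:
        return [p for p in self.plants if p.generation == g]

    def to_frame(self):
        import pandas as pd

        rows = [
            {
                "label": p.label,
                "parent_label": p.parent().label,  # type: ignore[union-attr]
                "generation": p.generation,
                "greenhouse": p.greenhouse,
            }
            for p in self.plants
        ]
        return pd.DataFrame(rows)


@dataclass
class BranchPlan:
    """Per-generation offspring plan for the cohort simulator.

    The default reproduces the study design: six generation-1 seeds split
    between two greenhouses, a six-way expansion at generation 2, single-seed
    descent with gradual lineage loss thereafter, and two generation-6 plants
    expanded to 16 progeny each instead of continuing SSD. The survivor counts
    were chosen so the cohort totals 233 plants.
    """

    gen1_seeds: dict[str, int] = field(default_factory=lambda: {"G1": 3, "G2": 3})
    gen2_offspring: int = 6
    # generation -> number of SSD lineages that continue into that generation
    # (expansion progeny are counted separately)
    ssd_survivors: dict[int, int] = field(
        default_factory=lambda: {3: 36, 4: 34, 5: 33, 6: 32, 7: 24}
    )
    expansions: dict[str, int] = field(
        default_factory=lambda: {"T.3.3.1.1.1.1_G1": 16, "T.2.5.1.1.1.1_G1": 16}
    )
    protected: tuple[str, ...] = (
        "T.3.3.1.1.1.1_G1",
        "T.2.5.1.1.1.1_G1",
        "T.3.5.1.1.1.1.1_G2",
    )
    generations: int = 7

    @classmethod
    def simple_ssd(cls, n_founder_seeds: int, generations: int) -> "BranchPlan":
        """Pure single-seed descent: every lineage survives, no expansion."""
        g1 = n_founder_seeds // 2
        return cls(
            gen1_seeds={"G1": n_founder_seeds - g1, "G2": g1},
            gen2_offspring=1,
            ssd_survivors={},
            expansions={},
            protected=(),
            generations=generations,
        )

    def validate(self) -> None:
        if self.generations < 1:
            raise ValueError("generations must be >= 1")
        if any(n < 0 for n in self.gen1_seeds.values()) or sum(self.gen1_seeds.values()) < 1:
            raise ValueError("need at least one generation-1 seed")
        if self.generations >= 2 and self.gen2_offspring < 1:
            raise ValueError("invalid plan: zero offspring for a surviving lineage")
        if any(k < 1 for k in self.expansions.values()):
            raise ValueError("invalid plan: zero offspring for an expanded plant")

    @property
    def total_plants(self) -> int:
        n1 = sum(self.gen1_seeds.values())
        if self.generations == 1:
            return n1
        total = n1
        tips = n1 * self.gen2_offspring
        total += tips
        for g in range(3, self.generations + 1):
            n_expand = sum(
                k for lab, k in self.expansions.items()
                if parse_plant_id(lab).generation == g - 1
            )
            tips = self.ssd_survivors.get(g, tips - (len(self.expansions) if n_expand else 0))
            total += tips + n_expand
        return total


def generate_pedigree(
    n_founder_seeds: int = 6,
    generations: int = 7,
    branch_plan: BranchPlan | None = None,
    seed: int = 0,
) -> Pedigree:
    """Simulate a single-seed-descent pedigree.

    With the default arguments this reproduces the study layout: 233 plants
    over seven generations, greenhouse split 3/3 at generation 1 and two
    generation-6 plants expanded sixteen-fold. Lineage loss is drawn from
    ``seed`` but never removes a lineage named in ``branch_plan.protected``
    or leading to an expansion plant, so the canonical plant labels always
    exist.
    """
    if branch_plan is None:
        if generations == 7 and n_founder_seeds == 6:
            branch_plan = BranchPlan()
        else:
            branch_plan = BranchPlan.simple_ssd(n_founder_seeds, generations)
    plan = branch_plan
    plan.validate()
    if generations != plan.generations:
        raise ValueError("generations argument disagrees with branch plan")

    rng = np.random.default_rng(seed)
    protected_ids = [parse_plant_id(lab) for lab in (*plan.protected, *plan.expansions)]

    def is_protected(p: PlantID) -> bool:
        return any(q == p or p.is_ancestor_of(q) for q in protected_ids)

    plants: list[PlantID] = []
    gen_prev: list[PlantID] = []
    for gh in sorted(plan.gen1_seeds):
        for i in range(plan.gen1_seeds[gh]):
            gen_prev.append(PlantID((i + 1,), gh))
    plants.extend(gen_prev)

    for g in range(2, plan.generations + 1):
        gen_now: list[PlantID] = []
        if g == 2:
            for tip in gen_prev:
                gen_now.extend(tip.child(i + 1) for i in range(plan.gen2_offspring))
        else:
            expanded = [t for t in gen_prev if t.label in plan.expansions]
            pool = [t for t in gen_prev if t.label not in plan.expansions]
            n_cont = plan.ssd_survivors.get(g, len(pool))
            must = [t for t in pool if is_protected(t)]
            free = [t for t in pool if not is_protected(t)]
            n_extra = n_cont - len(must)
            if n_extra < 0 or n_extra > len(free):
                raise ValueError(
                    f"invalid plan: cannot pick {n_cont} survivors at generation {g}"
                )
            picked = list(must)
            if n_extra:
                idx = rng.choice(len(free), size=n_extra, replace=False)
                picked.extend(free[i] for i in sorted(idx))
            for tip in sorted(picked):
                gen_now.append(tip.child(1))
            for tip in sorted(expanded):
                gen_now.extend(tip.child(i + 1) for i in range(plan.expansions[tip.label]))
        plants.extend(gen_now)
        gen_prev = gen_now

    ped = Pedigree(plants)
    if len(ped) != plan.total_plants:
        raise RuntimeError(
            f"pedigree size {len(ped)} disagrees with plan total {plan.total_plants}"
        )
    return ped
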