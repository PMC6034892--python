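"""Construction of the canned DCM model spaces and family partitions.

The core comparison space places the modulatory "Same" input on feedback
connections from every nonempty subset of the frontoparietal sources
{IPS, FEF, IFJ, mFG} to the ignored-side visual node (15 models for four
sources).  Further spaces test the direction of modulation between IFJ
and the other frontoparietal areas (three 7-model families), feedback to
V1 (3 models), and contralateral vs ipsilateral variants.

Enumeration order is deterministic: subsets are listed by increasing
size and, within a size, lexicographically by source position —
singletons first, then pairs, triples, and the full set, matching the
conventional listing (with sources ordered IPS, FEF, IFJ, mFG, Model 3
is the IFJ-only model).
"""

from __future__ import annotations

from dataclasses import dataclass
from itertools import combinations
from typing import Mapping, Sequence

import numpy as np

from .containers import ALL_VISUAL
from .dcm import DCMSpec

__all__ = [
    "ModelSpace",
    "FamilyPartition",
    "make_network_spec",
    "enumerate_feedback_models",
    "build_direction_families",
    "build_v1_models",
    "build_lateralized_families",
    "FRONTOPARIETAL",
]

#: Canonical source ordering used throughout.
FRONTOPARIETAL = ("IPS", "FEF", "IFJ", "mFG")
MODULATORY_INPUT = "Same"


@dataclass(frozen=True)
class ModelSpace:
    """An ordered list of (model_id, DCMSpec) sharing regions and inputs."""

    models: tuple[tuple[str, DCMSpec], ...]
    description: str = ""

    def __post_init__(self) -> None:
        ids = [mid for mid, _ in self.models]
        if len(set(ids)) != len(ids):
            raise ValueError("model ids must be unique")
        regions = {spec.regions for _, spec in self.models}
        if len(regions) > 1:
            raise ValueError("all models must share the same region set")

    def __len__(self) -> int:
        return len(self.models)

    @property
    def model_ids(self) -> tuple[str, ...]:
        return tuple(mid for mid, _ in self.models)

    def spec(self, model_id: str) -> DCMSpec:
        for mid, s in self.models:
            if mid == model_id:
                return s
        raise KeyError(model_id)

    def subset(self, model_ids: Sequence[str]) -> "ModelSpace":
        keep = set(model_ids)
        return ModelSpace(
            tuple((mid, s) for mid, s in self.models if mid in keep),
            description=self.description,
        )

    def to_dict(self) -> dict:
        return {
            "description": self.description,
            "models": [{"id": mid, "spec": s.to_dict()} for mid, s in self.models],
        }


@dataclass(frozen=True)
class FamilyPartition:
    """Disjoint, exhaustive grouping of model ids into named families."""

    families: Mapping[str, tuple[str, ...]]

    def __post_init__(self) -> None:
        seen: set[str] = set()
        for name, ids in self.families.items():
            if not ids:
                raise ValueError(f"family {name!r} is empty")
            if seen & set(ids):
                raise ValueError("families overlap")
            seen |= set(ids)
        object.__setattr__(self, "families", {k: tuple(v) for k, v in self.families.items()})

    @property
    def family_names(self) -> tuple[str, ...]:
        return tuple(self.families)

    def family_of(self, model_id: str) -> str:
        for name, ids in self.families.items():
            if model_id in ids:
                return name
        raise KeyError(model_id)

    def covers(self, model_ids: Sequence[str]) -> bool:
        return set(model_ids) == {m for ids in self.families.values() for m in ids}

    def to_dict(self) -> dict:
        return {k: list(v) for k, v in self.families.items()}


def make_network_spec(
    regions: Sequence[str],
    visual_regions: Sequence[str],
    modulated_edges: Sequence[tuple[str, str]],
    name: str = "",
    modulatory_input: str = MODULATORY_INPUT,
) -> DCMSpec:
    """Fully and reciprocally connected network with driving visual input.

    Intrinsic A allows every directed edge among the regions; the
    all-visual driving input enters ``visual_regions``; the modulatory
    input acts on ``modulated_edges`` given as (source, target) pairs.
    """
    regions = tuple(regions)
    n = len(regions)
    a_mask = ~np.eye(n, dtype=bool)
    b = np.zeros((n, n), bool)
    for src, dst in modulated_edges:
        b[regions.index(dst), regions.index(src)] = True
    c = np.zeros(n, bool)
    for v in visual_regions:
        c[regions.index(v)] = True
    return DCMSpec(
        regions=regions,
        a_mask=a_mask,
        b_masks={modulatory_input: b},
        c_masks={ALL_VISUAL: c},
        name=name,
    )


def _ordered_subsets(items: Sequence[str]) -> list[tuple[str, ...]]:
    """Nonempty subsets by (size, lexicographic-by-position)."""
    out: list[tuple[str, ...]] = []
    for size in range(1, len(items) + 1):
        out.extend(combinations(items, size))
    return out


def enumerate_feedback_models(
    sources: Sequence[str] = FRONTOPARIETAL,
    visual_target: str = "IMT+",
    regions: Sequence[str] | None = None,
    visual_regions: Sequence[str] | None = None,
) -> ModelSpace:
    """One model per nonempty subset of sources modulating feedback to
    the visual target (2^k - 1 models; 15 for the standard four sources)."""
    sources = tuple(sources)
    if not sources:
        raise ValueError("need at least one source")
    if regions is None:
        regions = sources + (visual_target,)
    if visual_regions is None:
        visual_regions = (visual_target,)
    models = []
    for k, subset in enumerate(_ordered_subsets(sources), start=1):
        edges = [(src, visual_target) for src in subset]
        spec = make_network_spec(
            regions, visual_regions, edges, name=f"feedback_{'+'.join(subset)}"
        )
        models.append((str(k), spec))
    return ModelSpace(
        tuple(models),
        description=f"feedback modulation onto {visual_target} from subsets of {sources}",
    )


def build_direction_families(
    hub: str = "IFJ",
    others: Sequence[str] = ("IPS", "FEF", "mFG"),
    regions: Sequence[str] | None = None,
    visual_regions: Sequence[str] | None = None,
) -> tuple[tuple[ModelSpace, ModelSpace, ModelSpace], FamilyPartition]:
    """Three families testing the direction of modulation around the hub.

    Family ``hub_to_others``: modulation on hub -> subset edges, one
    model per nonempty subset of ``others``; family ``others_to_hub``:
    the reversed edges; family ``both``: model k is the union of the
    corresponding models from the first two families.  The partition
    covers the concatenation (ids "<family>:<k>").
    """
    others = tuple(others)
    if not others:
        raise ValueError("need at least one non-hub area")
    if regions is None:
        regions = (hub,) + others + ("IMT+",)
    if visual_regions is None:
        visual_regions = ("IMT+",)
    subsets = _ordered_subsets(others)

    def space(family: str, edge_fn) -> ModelSpace:
        models = []
        for k, subset in enumerate(subsets, start=1):
            spec = make_network_spec(
                regions, visual_regions, edge_fn(subset), name=f"{family}_{k}"
            )
            models.append((f"{family}:{k}", spec))
        return ModelSpace(tuple(models), description=family)

    fam1 = space("hub_to_others", lambda ss: [(hub, o) for o in ss])
    fam2 = space("others_to_hub", lambda ss: [(o, hub) for o in ss])
    fam3 = space(
        "both", lambda ss: [(hub, o) for o in ss] + [(o, hub) for o in ss]
    )
    partition = FamilyPartition(
        {
            "hub_to_others": fam1.model_ids,
            "others_to_hub": fam2.model_ids,
            "both": fam3.model_ids,
        }
    )
    return (fam1, fam2, fam3), partition


def build_v1_models(
    visual_area: str = "IMT+",
    hub: str = "IFJ",
    v1: str = "V1",
) -> ModelSpace:
    """Three models for the origin of feedback to V1.

    Model 1: hub -> V1 modulation; Model 2: visual_area -> V1; Model 3:
    both.  The driving visual input enters both visual nodes.
    """
    regions = (hub, visual_area, v1)
    visual_regions = (visual_area, v1)
    edge_sets = [
        [(hub, v1)],
        [(visual_area, v1)],
        [(hub, v1), (visual_area, v1)],
    ]
    models = tuple(
        (str(k), make_network_spec(regions, visual_regions, edges, name=f"v1_{k}"))
        for k, edges in enumerate(edge_sets, start=1)
    )
    return ModelSpace(models, description=f"feedback to {v1} from {hub} vs {visual_area}")


def build_lateralized_families(
    base_space: ModelSpace,
    tags: tuple[str, str] = ("contra", "ipsi"),
) -> tuple[ModelSpace, FamilyPartition]:
    """Duplicate each model with contralateral / ipsilateral region tags.

    Model k in each family shares the masks of base model k; only the
    region labels differ (prefixed "C_" / "I_").  Returns the combined
    2K-model space and the two-family partition.
    """
    prefix = {tags[0]: "C_", tags[1]: "I_"}
    models: list[tuple[str, DCMSpec]] = []
    families: dict[str, list[str]] = {t: [] for t in tags}
    for tag in tags:
        for mid, spec in base_space.models:
            tagged = DCMSpec(
                regions=tuple(prefix[tag] + r for r in spec.regions),
                a_mask=spec.a_mask,
                b_masks=dict(spec.b_masks),
                c_masks=dict(spec.c_masks),
                name=f"{tag}_{spec.name}",
            )
            new_id = f"{tag}:{mid}"
            models.append((new_id, tagged))
            families[tag].append(new_id)
    # regions differ between families by design; bypass the shared-region check
    space = ModelSpace.__new__(ModelSpace)
    object.__setattr__(space, "models", tuple(models))
    object.__setattr__(space, "description", f"lateralized: {base_space.description}")
    return space, FamilyPartition({k: tuple(v) for k, v in families.items()})
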