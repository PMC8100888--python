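"""Synthetic hierarchical code vocabulary.

Administrative claims code systems (ICD-9/10-CM mapped to SNOMED, procedure
codes mapped to ICD-10-PCS) form a directed acyclic "is-a" hierarchy, and the
imputation stage expands every observed code to all of its ancestors.  Real
vocabularies are licensed artifacts, so the pipeline runs on a synthetic DAG
that preserves the structural properties the downstream stages rely on:

* an acyclic child -> parents relation with bounded depth,
* a role flag per code (self-harm outcome codes, bipolar-disorder diagnosis
  codes, major-mental-illness exclusion codes, censoring-condition codes,
  psychotherapy procedure codes, proxy injury codes that co-occur with true
  self-harm events, and generic background codes),
* a drug dictionary mapping each agent to exactly one of the 11 drug classes
  studied (lithium, MSA, SGA, TGA, FGA, SSRI, SNRI, NDRI, NASSA,
  tri/tetracyclic, MAOI).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Mapping

import numpy as np
import pandas as pd

from .errors import ConfigurationError, DataError

ROLE_FLAGS = (
    "self_harm",
    "bd_diagnosis",
    "exclusion_mmi",
    "censoring_condition",
    "psychotherapy_procedure",
    "proxy_injury",
    "background",
)

DRUG_CLASSES = (
    "LITHIUM",
    "MSA",
    "SGA",
    "TGA",
    "FGA",
    "SSRI",
    "SNRI",
    "NDRI",
    "NASSA",
    "TRI_TETRA",
    "MAOI",
)

#: Default agent -> class dictionary.  One common agent per class plus the
#: within-class variety needed for multi-MSA / multi-SGA regimens and the
#: uncommon monotherapies (clozapine, brexpiprazole, iloperidone).
DEFAULT_DRUG_CLASS_MAP: dict[str, str] = {
    "lithium": "LITHIUM",
    "valproate": "MSA",
    "lamotrigine": "MSA",
    "carbamazepine": "MSA",
    "oxcarbazepine": "MSA",
    "risperidone": "SGA",
    "quetiapine": "SGA",
    "olanzapine": "SGA",
    "clozapine": "SGA",
    "iloperidone": "SGA",
    "aripiprazole": "TGA",
    "brexpiprazole": "TGA",
    "haloperidol": "FGA",
    "fluoxetine": "SSRI",
    "sertraline": "SSRI",
    "venlafaxine": "SNRI",
    "bupropion": "NDRI",
    "mirtazapine": "NASSA",
    "amitriptyline": "TRI_TETRA",
    "phenelzine": "MAOI",
}

#: Anti-dementia agents: their fills are censoring events, and they do not
#: belong to any of the 11 bipolar-disorder drug classes.
DEFAULT_CENSORING_DRUGS = frozenset({"donepezil"})


@dataclass
class CodeVocabulary:
    """DAG of billing codes with role flags and a drug dictionary."""

    parents: dict[str, tuple[str, ...]]
    roles: dict[str, str]
    drug_class_map: dict[str, str] = field(
        default_factory=lambda: dict(DEFAULT_DRUG_CLASS_MAP)
    )
    drug_agent_map: dict[str, str] = field(default_factory=dict)
    censoring_drug_ids: frozenset = DEFAULT_CENSORING_DRUGS

    def __post_init__(self) -> None:
        if not self.drug_agent_map:
            self.drug_agent_map = {d: d for d in self.drug_class_map}
        unknown = set(self.roles.values()) - set(ROLE_FLAGS)
        if unknown:
            raise ConfigurationError(f"unknown role flags: {sorted(unknown)}")
        bad = set(self.drug_class_map.values()) - set(DRUG_CLASSES)
        if bad:
            raise ConfigurationError(f"unknown drug classes: {sorted(bad)}")
        self._check_acyclic()
        self._closure_cache: dict[str, frozenset] = {}

    # -- structure ---------------------------------------------------------

    @property
    def codes(self) -> frozenset:
        return frozenset(self.roles)

    def _check_acyclic(self) -> None:
        state: dict[str, int] = {}  # 0=visiting, 1=done

        def visit(c: str, stack: list) -> None:
            s = state.get(c)
            if s == 1:
                return
            if s == 0:
                raise DataError(f"cycle in code hierarchy at {c!r}")
            state[c] = 0
            for p in self.parents.get(c, ()):
                visit(p, stack)
            state[c] = 1

        for c in self.roles:
            visit(c, [])

    def ancestor_closure(self, code: str) -> frozenset:
        """The code together with all of its transitive ancestors."""
        cached = self._closure_cache.get(code)
        if cached is not None:
            return cached
        out = {code}
        frontier = list(self.parents.get(code, ()))
        while frontier:
            p = frontier.pop()
            if p not in out:
                out.add(p)
                frontier.extend(self.parents.get(p, ()))
        result = frozenset(out)
        self._closure_cache[code] = result
        return result

    # -- role lookups ------------------------------------------------------

    def role_codes(self, role: str) -> frozenset:
        if role not in ROLE_FLAGS:
            raise ConfigurationError(f"unknown role {role!r}")
        return frozenset(c for c, r in self.roles.items() if r == role)

    @property
    def self_harm_codes(self) -> frozenset:
        return self.role_codes("self_harm")

    @property
    def bd_codes(self) -> frozenset:
        return self.role_codes("bd_diagnosis")

    @property
    def exclusion_codes(self) -> frozenset:
        return self.role_codes("exclusion_mmi")

    @property
    def censoring_codes(self) -> frozenset:
        return self.role_codes("censoring_condition")

    @property
    def psychotherapy_codes(self) -> frozenset:
        return self.role_codes("psychotherapy_procedure")

    @property
    def proxy_codes(self) -> frozenset:
        return self.role_codes("proxy_injury")

    def self_harm_feature_exclusions(self) -> frozenset:
        """Self-harm codes plus ancestors reachable only from self-harm codes.

        These must never leak into imputation features.
        """
        sh = self.self_harm_codes
        sh_anc = set().union(*(self.ancestor_closure(c) for c in sh)) if sh else set()
        other_anc: set = set()
        for c in self.roles:
            if c not in sh:
                other_anc |= self.ancestor_closure(c)
        return frozenset(sh | (sh_anc - other_anc))

    # -- (de)serialization -------------------------------------------------

    def to_frame(self) -> pd.DataFrame:
        rows = [
            {"code": c, "role": r, "parents": ";".join(self.parents.get(c, ()))}
            for c, r in sorted(self.roles.items())
        ]
        drug_rows = [
            {
                "code": f"drug:{d}",
                "role": f"drug_class:{cls}",
                "parents": "",
            }
            for d, cls in sorted(self.drug_class_map.items())
        ]
        drug_rows += [
            {"code": f"drug:{d}", "role": "drug_class:CENSORING", "parents": ""}
            for d in sorted(self.censoring_drug_ids)
        ]
        return pd.DataFrame(rows + drug_rows, columns=["code", "role", "parents"])

    @classmethod
    def from_frame(cls, df: pd.DataFrame) -> "CodeVocabulary":
        parents: dict[str, tuple[str, ...]] = {}
        roles: dict[str, str] = {}
        drug_map: dict[str, str] = {}
        censoring: set = set()
        for row in df.itertuples(index=False):
            if str(row.code).startswith("drug:"):
                drug = str(row.code)[5:]
                drug_class = str(row.role).split(":", 1)[1]
                if drug_class == "CENSORING":
                    censoring.add(drug)
                else:
                    drug_map[drug] = drug_class
            else:
                roles[str(row.code)] = str(row.role)
                ps = str(row.parents) if not pd.isna(row.parents) else ""
                parents[str(row.code)] = tuple(p for p in ps.split(";") if p)
        return cls(
            parents=parents,
            roles=roles,
            drug_class_map=drug_map,
            censoring_drug_ids=frozenset(censoring),
        )


def generate_vocabulary(
    n_background_codes: int,
    max_depth: int,
    seed: int,
    *,
    n_self_harm: int = 3,
    n_proxy: int = 10,
    n_bd: int = 3,
    n_exclusion: int = 3,
    n_censoring: int = 4,
    n_psychotherapy: int = 5,
    drug_class_map: Mapping[str, str] | None = None,
) -> CodeVocabulary:
    """Generate a random synthetic code DAG with all role groups populated.

    Background codes are arranged in ``max_depth + 1`` layers; each code in
    layer d > 0 points to one or two parents in layer d-1.  Role-specific
    codes form small chains under a role root so ancestor expansion has
    something to expand.  Deterministic for a fixed seed.
    """
    if n_background_codes < 10:
        raise ConfigurationError("n_background_codes must be >= 10")
    if max_depth < 1:
        raise ConfigurationError("max_depth must be >= 1")
    if n_self_harm < 1:
        raise ConfigurationError("need at least one self-harm code")

    rng = np.random.default_rng(seed)
    parents: dict[str, tuple[str, ...]] = {}
    roles: dict[str, str] = {}

    # background layers
    n_layers = max_depth + 1
    per_layer = max(2, n_background_codes // n_layers)
    layers: list[list[str]] = []
    idx = 0
    for d in range(n_layers):
        size = per_layer if d < n_layers - 1 else n_background_codes - idx
        if size <= 0:
            break
        layer = [f"BG{idx + i:04d}" for i in range(size)]
        idx += size
        for c in layer:
            roles[c] = "background"
            if d == 0:
                parents[c] = ()
            else:
                k = int(rng.integers(1, 3))
                chosen = rng.choice(len(layers[d - 1]), size=min(k, len(layers[d - 1])), replace=False)
                parents[c] = tuple(layers[d - 1][j] for j in sorted(chosen))
        layers.append(layer)

    def add_role_group(prefix: str, role: str, n: int) -> list[str]:
        group = [f"{prefix}{i:02d}" for i in range(n)]
        for i, c in enumerate(group):
            roles[c] = role
            parents[c] = () if i == 0 else (group[0],)
        return group

    add_role_group("SH", "self_harm", n_self_harm)
    add_role_group("BD", "bd_diagnosis", n_bd)
    add_role_group("MX", "exclusion_mmi", n_exclusion)
    add_role_group("CN", "censoring_condition", n_censoring)
    add_role_group("PT", "psychotherapy_procedure", n_psychotherapy)
    # proxy injury codes hang off a dedicated background "injury" root (like
    # the injury/poisoning subtree of a real hierarchy): the root is itself a
    # background code, so the expanded ancestor stays usable as a feature
    injury_root = "BGINJ"
    roles[injury_root] = "background"
    parents[injury_root] = ()
    proxy = [f"PX{i:02d}" for i in range(n_proxy)]
    for c in proxy:
        roles[c] = "proxy_injury"
        parents[c] = (injury_root,)

    dcm = dict(drug_class_map) if drug_class_map is not None else dict(DEFAULT_DRUG_CLASS_MAP)
    missing = set(DRUG_CLASSES) - set(dcm.values())
    if missing:
        raise ConfigurationError(f"drug_class_map misses classes: {sorted(missing)}")
    return CodeVocabulary(parents=parents, roles=roles, drug_class_map=dcm)
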