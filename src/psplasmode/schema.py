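"""Covariate schema for RHC-like cohorts.

A schema names every covariate, its measurement kind and, for the nine
continuous variables that enter the outcome data-generating model through
special terms (polynomials, interactions, exp/cos transforms), a
``dgm_special`` role.  The default schema mimics the mix of the SUPPORT
adjustment set: 22 continuous, 22 binary and 6 three-level categorical
covariates, 50 in total.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import yaml

#: continuous covariates required by the special terms of the true outcome model
DGM_SPECIAL = (
    "age",
    "pafi",
    "heart_rate",
    "mean_bp",
    "gcs",
    "hematocrit",
    "sodium",
    "weight",
    "apache",
)


@dataclass(frozen=True)
class Covariate:
    name: str
    kind: str  # continuous | binary | categorical
    levels: tuple[str, ...] = ()
    role: str = "plain"  # plain | dgm_special

    def __post_init__(self) -> None:
        if self.kind not in ("continuous", "binary", "categorical"):
            raise ValueError(f"unknown covariate kind {self.kind!r}")
        if self.kind == "categorical" and len(self.levels) < 2:
            raise ValueError(f"categorical covariate {self.name!r} needs >= 2 levels")
        if self.role == "dgm_special" and self.kind != "continuous":
            raise ValueError(f"dgm_special covariate {self.name!r} must be continuous")


@dataclass(frozen=True)
class CovariateSchema:
    covariates: tuple[Covariate, ...]

    def __post_init__(self) -> None:
        names = [c.name for c in self.covariates]
        if len(set(names)) != len(names):
            raise ValueError("covariate names must be unique")
        for c in self.covariates:
            if c.name in DGM_SPECIAL and c.kind != "continuous":
                raise ValueError(f"DGM covariate {c.name!r} must be continuous")

    @property
    def dgm_special_missing(self) -> list[str]:
        """Special-term covariates the outcome DGM needs but the schema lacks."""
        present = {c.name for c in self.covariates if c.kind == "continuous"}
        return sorted(set(DGM_SPECIAL) - present)

    def require_dgm_specials(self) -> None:
        missing = self.dgm_special_missing
        if missing:
            raise ValueError(f"schema missing dgm_special covariates: {missing}")

    def __len__(self) -> int:
        return len(self.covariates)

    @property
    def names(self) -> list[str]:
        return [c.name for c in self.covariates]

    @property
    def continuous(self) -> list[str]:
        return [c.name for c in self.covariates if c.kind == "continuous"]

    @property
    def binary(self) -> list[str]:
        return [c.name for c in self.covariates if c.kind == "binary"]

    @property
    def categorical(self) -> list[Covariate]:
        return [c for c in self.covariates if c.kind == "categorical"]

    def __getitem__(self, name: str) -> Covariate:
        for c in self.covariates:
            if c.name == name:
                return c
        raise KeyError(name)

    def to_yaml(self, path) -> None:
        payload = [
            {"name": c.name, "kind": c.kind, "levels": list(c.levels), "role": c.role}
            for c in self.covariates
        ]
        with open(path, "w") as fh:
            yaml.safe_dump(payload, fh, sort_keys=False)

    @classmethod
    def from_yaml(cls, path) -> "CovariateSchema":
        with open(path) as fh:
            payload = yaml.safe_load(fh)
        return cls(
            tuple(
                Covariate(
                    name=item["name"],
                    kind=item["kind"],
                    levels=tuple(item.get("levels") or ()),
                    role=item.get("role", "plain"),
                )
                for item in payload
            )
        )


def default_schema(
    n_continuous: int = 22, n_binary: int = 22, n_categorical: int = 6
) -> CovariateSchema:
    """Default RHC-like schema: 22 continuous (incl. the nine special), 22
    binary, 6 three-level categoricals -> 50 covariates."""
    if n_continuous < len(DGM_SPECIAL):
        raise ValueError(f"need at least {len(DGM_SPECIAL)} continuous covariates")
    covs: list[Covariate] = [
        Covariate(name, "continuous", role="dgm_special") for name in DGM_SPECIAL
    ]
    covs += [
        Covariate(f"cont{i}", "continuous")
        for i in range(1, n_continuous - len(DGM_SPECIAL) + 1)
    ]
    covs += [Covariate(f"bin{i}", "binary") for i in range(1, n_binary + 1)]
    covs += [
        Covariate(f"cat{i}", "categorical", levels=("a", "b", "c"))
        for i in range(1, n_categorical + 1)
    ]
    return CovariateSchema(tuple(covs))
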