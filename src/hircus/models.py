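"""Animal-model structure declarations.

A :class:`ModelSpec` says which traits are analysed, which fixed effects
each trait carries, and which random terms each trait loads on:

* ``AAG`` — direct autosomal additive genetic effect (pedigree A structure)
* ``SLAG`` — direct X-linked additive genetic effect (S structure)
* ``MGE`` — maternal additive genetic effect (A structure, on the dam)
* ``MPE`` — maternal permanent environmental effect (i.i.d. over dams)

plus the residual.  Each random term owns a trait x trait covariance block,
free only on the traits that load on the term; all other entries are
constrained to zero.  When the direct-maternal covariance is switched on,
AAG and MGE merge into one joint block with a full cross-covariance.

The four multivariate structures used in the sensitivity ladder are
available as presets: ``model1`` (AAG+SLAG+MGE+MPE, Cov(a,m)=0), ``model2``
(drops SLAG), ``model3`` (AAG+SLAG only) and ``model4`` (model1 with
Cov(a,m) free).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

AAG = "AAG"
SLAG = "SLAG"
MGE = "MGE"
MPE = "MPE"
RANDOM_TERMS = (AAG, SLAG, MGE, MPE)

#: pedigree structure backing each term ("A", "S" or i.i.d. dam levels)
TERM_STRUCTURE = {AAG: "A", SLAG: "S", MGE: "A", MPE: "I_dam"}
#: whose effect the term is: the animal's own or its dam's
TERM_CARRIER = {AAG: "animal", SLAG: "animal", MGE: "dam", MPE: "dam"}


@dataclass
class ModelSpec:
    traits: tuple
    fixed_effects: dict  # trait -> list of factor column names
    random_terms: dict  # term -> tuple of traits loading on it
    direct_maternal_covariance: bool = False
    name: str = "custom"

    def __post_init__(self) -> None:
        self.traits = tuple(self.traits)
        self.random_terms = {
            t: tuple(tr) for t, tr in self.random_terms.items() if len(tr) > 0
        }
        for term, trs in self.random_terms.items():
            if term not in RANDOM_TERMS:
                raise ValueError(f"unknown random term {term!r}")
            unknown = set(trs) - set(self.traits)
            if unknown:
                raise ValueError(f"traits {unknown} of term {term} not in model traits")
        if self.direct_maternal_covariance and (
            AAG not in self.random_terms or MGE not in self.random_terms
        ):
            raise ValueError("Cov(a,m) requires both AAG and MGE terms")

    # -- covariance blocks -------------------------------------------------
    def blocks(self) -> list[tuple[str, list[tuple[str, str]], str]]:
        """Estimated covariance blocks as (name, [(term, trait), ...], structure).

        AAG and MGE merge into one A-structured block when Cov(a,m) is free.
        The residual block (all traits) is appended last with structure "R".
        """
        out = []
        merged = self.direct_maternal_covariance
        for term in RANDOM_TERMS:
            if term not in self.random_terms:
                continue
            if merged and term == AAG:
                pairs = [(AAG, t) for t in self.random_terms[AAG]]
                pairs += [(MGE, t) for t in self.random_terms[MGE]]
                out.append(("AAG+MGE", pairs, "A"))
            elif merged and term == MGE:
                continue
            else:
                pairs = [(term, t) for t in self.random_terms[term]]
                out.append((term, pairs, TERM_STRUCTURE[term]))
        out.append(("R", [("R", t) for t in self.traits], "R"))
        return out

    def n_parameters(self) -> int:
        return sum(len(p) * (len(p) + 1) // 2 for _, p, _ in self.blocks())


def count_parameters(spec: ModelSpec) -> int:
    """Number of free (co)variance parameters of a model structure.

    Every block contributes t(t+1)/2 for its t loading traits; a free
    direct-maternal cross block adds t_a * t_m on top of the two symmetric
    blocks (equivalently the merged block contributes (t_a+t_m)(t_a+t_m+1)/2).
    """
    return spec.n_parameters()


def model_preset(
    name: str,
    traits,
    fixed_effects: dict,
    pe_traits=("BWT",),
) -> ModelSpec:
    """The multivariate sensitivity-ladder presets model1 ... model4."""
    traits = tuple(traits)
    pe = tuple(t for t in pe_traits if t in traits)
    menu = {
        "model1": dict(
            random_terms={AAG: traits, SLAG: traits, MGE: traits, MPE: pe},
            direct_maternal_covariance=False,
        ),
        "model2": dict(
            random_terms={AAG: traits, MGE: traits, MPE: pe},
            direct_maternal_covariance=False,
        ),
        "model3": dict(
            random_terms={AAG: traits, SLAG: traits},
            direct_maternal_covariance=False,
        ),
        "model4": dict(
            random_terms={AAG: traits, SLAG: traits, MGE: traits, MPE: pe},
            direct_maternal_covariance=True,
        ),
    }
    if name not in menu:
        raise ValueError(f"unknown preset {name!r}; choose from {sorted(menu)}")
    return ModelSpec(traits=traits, fixed_effects=dict(fixed_effects), name=name, **menu[name])


def univariate_menu(trait: str, fixed_effects, pe: bool = True) -> list[ModelSpec]:
    """The six single-trait random-effect structures screened per trait."""
    fx = {trait: list(fixed_effects)}
    t = (trait,)
    combos = [
        ({AAG: t}, False, "u1:a"),
        ({AAG: t, MGE: t}, False, "u2:a+m"),
        ({AAG: t, SLAG: t, MGE: t}, False, "u3:a+s+m"),
        ({AAG: t, MGE: t, MPE: t}, False, "u4:a+m+pe"),
        ({AAG: t, SLAG: t, MGE: t, MPE: t}, False, "u5:a+s+m+pe"),
        ({AAG: t, SLAG: t, MGE: t}, True, "u6:a+s+m,cov(a,m)"),
    ]
    if not pe:
        combos = [c for c in combos if MPE not in c[0]]
    return [
        ModelSpec(traits=t, fixed_effects=fx, random_terms=rt,
                  direct_maternal_covariance=cov, name=nm)
        for rt, cov, nm in combos
    ]


@dataclass
class VarianceComponents:
    """Fitted (co)variance blocks plus likelihood metadata.

    ``blocks`` maps block name -> symmetric matrix over that block's
    (term, trait) pairs, in the order given by ``spec.blocks()``.  The AI
    matrix (and its inverse) are over the free parameters in the same
    block-by-block lower-triangle order as :meth:`free_vector`.
    """

    spec: ModelSpec
    blocks: dict
    logL: float = np.nan
    AIC: float = np.nan
    n_free_parameters: int = 0
    AI_matrix: np.ndarray | None = None
    converged: bool = False
    n_iter: int = 0
    boundary_flags: list = field(default_factory=list)

    def block_pairs(self, name: str) -> list[tuple[str, str]]:
        for nm, pairs, _ in self.spec.blocks():
            if nm == name:
                return pairs
        raise KeyError(name)

    def get(self, term: str, trait_x: str, trait_y: str | None = None) -> float:
        """Covariance entry for a term and trait pair (variance if one trait)."""
        trait_y = trait_y or trait_x
        for nm, pairs, _ in self.spec.blocks():
            look = {"R": "R"}.get(term, term)
            key_x = (look, trait_x)
            key_y = (look, trait_y)
            if key_x in pairs and key_y in pairs:
                B = self.blocks[nm]
                return float(B[pairs.index(key_x), pairs.index(key_y)])
        return 0.0

    def direct_maternal_cov(self, trait_x: str, trait_y: str | None = None) -> float:
        trait_y = trait_y or trait_x
        for nm, pairs, _ in self.spec.blocks():
            if (AAG, trait_x) in pairs and (MGE, trait_y) in pairs:
                B = self.blocks[nm]
                return float(B[pairs.index((AAG, trait_x)), pairs.index((MGE, trait_y))])
        return 0.0

    def free_vector(self) -> np.ndarray:
        out = []
        for nm, pairs, _ in self.spec.blocks():
            B = self.blocks[nm]
            k = len(pairs)
            for i in range(k):
                for j in range(i + 1):
                    out.append(B[i, j])
        return np.array(out)

    def with_free_vector(self, theta: np.ndarray) -> "VarianceComponents":
        blocks = {}
        pos = 0
        for nm, pairs, _ in self.spec.blocks():
            k = len(pairs)
            B = np.zeros((k, k))
            for i in range(k):
                for j in range(i + 1):
                    B[i, j] = B[j, i] = theta[pos]
                    pos += 1
            blocks[nm] = B
        return VarianceComponents(self.spec, blocks, n_free_parameters=self.n_free_parameters)

    def parameter_labels(self) -> list[str]:
        out = []
        for nm, pairs, _ in self.spec.blocks():
            for i in range(len(pairs)):
                for j in range(i + 1):
                    ti, tj = pairs[i], pairs[j]
                    if i == j:
                        out.append(f"var({ti[0]},{ti[1]})")
                    else:
                        out.append(f"cov({ti[0]},{ti[1]};{tj[0]},{tj[1]})")
        return out


def aic(logL: float, n_parameters: int) -> float:
    """Akaike information criterion, -2 logL + 2 P."""
    return -2.0 * logL + 2.0 * n_parameters
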