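"""Built-in network model fixtures.

``toy``
    Five-species demonstration network (inputs A, B; receptors C, D;
    output E) with a bistable C/E positive feedback loop inhibited by D.

``betaAR``
    Cardiac beta1-adrenergic signaling: 25 species, 36 reactions.
    Norepinephrine drives receptor/G-protein/cAMP/PKA signaling onto five
    PKA substrates (PLB, TnI, IKs, ICa, RyR), with GRK- and PKA-mediated
    receptor desensitization feedback, the inhibitor-1/PP1 feed-forward
    loop, and pharmacological inputs FSK (adenylyl cyclase activator) and
    IBMX (phosphodiesterase inhibitor).  Its sensitivity set covers 22 of
    the 25 species (GsaGDP, PKAR and GRK are excluded).

``betaAR_integrin``
    The beta-adrenergic network extended with integrin-mediated
    mechanotransduction: a mechanical ``Stress`` input activates integrins
    (``Itg``), which couple to G-protein activation, and PKA phosphorylates
    the integrin beta-subunit (``Itgbp``).
"""

from __future__ import annotations

from importlib import resources

from .model import NetworkModel, SpeciesSpec, load_model, make_reaction

__all__ = ["builtin_model", "BUILTIN_NAMES"]

BUILTIN_NAMES = ("toy", "betaAR", "betaAR_integrin")

# 22-species all-against-all perturbation set of the beta-adrenergic model
BETA_AR_SENSITIVITY_SET = (
    "NE", "FSK", "IBMX", "B1AR", "B1ARPG", "B1ARPA", "GsaBg", "GsaGTP",
    "Gbg", "AC", "cAMP", "PDE", "PKI", "PKAC", "PP1", "PP2A", "Inhib1",
    "PLB", "TnI", "IKs", "ICa", "RyR",
)

_INTEGRIN_SPECIES = (
    SpeciesSpec(name="Stress", role="input"),
    SpeciesSpec(name="Itg", role="state"),
    SpeciesSpec(name="Itgbp", role="state"),
)
_INTEGRIN_RULES = (
    ("Stress_Itg", "Stress => Itg"),
    ("Itg_GsaBg_GsaGTP", "Itg & GsaBg => GsaGTP"),
    ("PKAC_Itg_Itgbp", "PKAC & Itg => Itgbp"),
)


def _load_fixture(dirname: str, name: str) -> NetworkModel:
    root = resources.files("hillnet").joinpath("data", dirname)
    with resources.as_file(root.joinpath("species.csv")) as sp, resources.as_file(
        root.joinpath("reactions.csv")
    ) as rx:
        return load_model(sp, rx, name=name)


def builtin_model(name: str) -> NetworkModel:
    """Return one of the canonical fixtures by name.

    Raises ``KeyError`` for an unrecognized name.
    """
    if name == "toy":
        return _load_fixture("toy", "toy")
    if name == "betaAR":
        m = _load_fixture("betaAR", "betaAR")
        m.sensitivity_set = BETA_AR_SENSITIVITY_SET
        m.validate()
        return m
    if name == "betaAR_integrin":
        base = builtin_model("betaAR")
        species = base.species + _INTEGRIN_SPECIES
        reactions = base.reactions + tuple(
            make_reaction(rid, rule) for rid, rule in _INTEGRIN_RULES
        )
        return NetworkModel(
            species=species,
            reactions=reactions,
            sensitivity_set=BETA_AR_SENSITIVITY_SET + ("Stress", "Itg", "Itgbp"),
            kernel=base.kernel,
            name="betaAR_integrin",
        )
    raise KeyError(f"unknown builtin model {name!r}; expected one of {BUILTIN_NAMES}")
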