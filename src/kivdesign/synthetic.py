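"""Synthetic inputs: a desk-scale toy metabolic network, batch-culture
growth curves with known kinetic parameters, and the published batch
endpoint records used for yield arithmetic.

The toy network is an analytically solvable stand-in for a genome-scale
*E. coli* reconstruction. It lumps glycolysis, the TCA cycle and oxidative
phosphorylation but keeps the redox and energy pools (NAD(H), NADP(H),
ATP/ADP) explicitly balanced, with a transhydrogenase supplying the NADPH
that ketol-acid reductoisomerase demands — so cofactor supply is a real
constraint on 2-ketoisovalerate (2-KIV) production, as it is in the full
network. With the glucose uptake cap u (default 10 mmol gDCW^-1 h^-1):

* max biomass flux = 2u  (glucose -> 2 pyruvate; biomass drains
  0.5 pyruvate + 0.5 acetyl-CoA + 1 ATP per unit)
* max 2-KIV export = u   (two pyruvates per 2-KIV)

Deleting ``aceF`` (pyruvate dehydrogenase) makes acetyl-CoA unreachable,
so the biomass optimum drops to 0 while 2-KIV export is untouched.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .model import DEFAULT_BOUND, MetabolicModel, Metabolite, Reaction


@dataclass
class ToyNetworkSpec:
    """Parameters of the toy central-carbon network."""

    glucose_uptake_cap: float = 10.0
    include_kiv_branch: bool = True


def make_toy_network(spec: ToyNetworkSpec | None = None) -> MetabolicModel:
    """Build the 15-reaction, 15-metabolite toy network.

    Compartments: cytosol ``c`` and extracellular ``e``. Gene rules:
    PDH:aceF, TCA lump:gltA, ACLS:alsS, KARA:ilvC, DHAD:ilvD.
    ``include_kiv_branch=False`` closes acetolactate synthase, making
    2-KIV export infeasible while leaving the matrix shape unchanged.
    """
    spec = spec or ToyNetworkSpec()
    u = spec.glucose_uptake_cap

    mets = [
        Metabolite("glc_e", "D-glucose", "e"),
        Metabolite("glc_c", "D-glucose", "c"),
        Metabolite("pyr_c", "pyruvate", "c"),
        Metabolite("accoa_c", "acetyl-CoA", "c"),
        Metabolite("alac_c", "2-acetolactate", "c"),
        Metabolite("dhmb_c", "2,3-dihydroxy-3-methylbutanoate", "c"),
        Metabolite("kiv_c", "2-ketoisovalerate", "c"),
        Metabolite("kiv_e", "2-ketoisovalerate", "e"),
        Metabolite("co2_e", "CO2 (vented)", "e"),
        Metabolite("nad_c", "NAD+", "c"),
        Metabolite("nadh_c", "NADH", "c"),
        Metabolite("nadp_c", "NADP+", "c"),
        Metabolite("nadph_c", "NADPH", "c"),
        Metabolite("atp_c", "ATP", "c"),
        Metabolite("adp_c", "ADP", "c"),
    ]

    B = DEFAULT_BOUND
    acls_ub = B if spec.include_kiv_branch else 0.0
    rxns = [
        Reaction("EX_glc_e", {"glc_e": -1}, -u, 0.0, is_exchange=True,
                 name="glucose exchange"),
        Reaction("GLCt", {"glc_e": -1, "glc_c": 1}, 0.0, B, name="glucose uptake"),
        Reaction("EMP", {"glc_c": -1, "nad_c": -2, "adp_c": -2,
                         "pyr_c": 2, "nadh_c": 2, "atp_c": 2}, 0.0, B,
                 name="glycolysis (lumped)"),
        Reaction("PDH", {"pyr_c": -1, "nad_c": -1,
                         "accoa_c": 1, "nadh_c": 1, "co2_e": 1}, 0.0, B,
                 gene_rule="aceF", name="pyruvate dehydrogenase"),
        Reaction("TCA", {"accoa_c": -1, "nad_c": -3, "adp_c": -1,
                         "nadh_c": 3, "atp_c": 1, "co2_e": 2}, 0.0, B,
                 gene_rule="gltA", name="TCA cycle (lumped)"),
        Reaction("ACLS", {"pyr_c": -2, "alac_c": 1, "co2_e": 1}, 0.0, acls_ub,
                 gene_rule="alsS", name="acetolactate synthase"),
        Reaction("KARA", {"alac_c": -1, "nadph_c": -1,
                          "dhmb_c": 1, "nadp_c": 1}, 0.0, B,
                 gene_rule="ilvC", name="ketol-acid reductoisomerase"),
        Reaction("DHAD", {"dhmb_c": -1, "kiv_c": 1}, 0.0, B,
                 gene_rule="ilvD", name="dihydroxy-acid dehydratase"),
        Reaction("THD", {"nadh_c": -1, "nadp_c": -1,
                         "nad_c": 1, "nadph_c": 1}, 0.0, B,
                 name="transhydrogenase"),
        Reaction("NOX", {"nadh_c": -1, "adp_c": -2,
                         "nad_c": 1, "atp_c": 2}, 0.0, B,
                 name="NADH oxidation / oxidative phosphorylation (lumped)"),
        Reaction("ATPM", {"atp_c": -1, "adp_c": 1}, 0.0, B,
                 name="ATP maintenance"),
        Reaction("BIOMASS", {"pyr_c": -0.5, "accoa_c": -0.5,
                             "atp_c": -1, "adp_c": 1}, 0.0, B,
                 name="biomass drain"),
        Reaction("KIVt", {"kiv_c": -1, "kiv_e": 1}, 0.0, B,
                 name="2-KIV export"),
        Reaction("EX_kiv_e", {"kiv_e": -1}, 0.0, B, is_exchange=True,
                 name="2-KIV exchange"),
        Reaction("EX_co2_e", {"co2_e": -1}, 0.0, B, is_exchange=True,
                 name="CO2 exchange"),
    ]

    return MetabolicModel(
        metabolites=mets,
        reactions=rxns,
        objective_id="BIOMASS",
        compartment_chain=["c", "e"],
        name="toy_ecoli_w",
    )


def toy_network_fixture_path():
    """Path to the shipped native-dialect copy of the toy network."""
    from pathlib import Path

    return Path(__file__).parent / "data" / "toy_network.txt"


@dataclass
class BatchSimParams:
    """Generative parameters of a simulated batch culture.

    Growth is exponential at rate ``mu`` (1/h) from inoculum ``X0`` (g
    DCW/L) until the substrate ``S0`` (g/L) is exhausted; substrate
    depletion is yield-coupled through ``Yxs`` (g DCW / g substrate) and
    product formation through ``Yps`` (g product / g substrate).
    Measurement noise is multiplicative lognormal with standard deviation
    ``noise_sd`` on the log scale (concentrations stay positive).
    """

    X0: float = 0.05
    mu: float = 0.5
    Yxs: float = 0.4
    Yps: float = 0.2
    S0: float = 10.0
    noise_sd: float = 0.0
    times: np.ndarray = field(default_factory=lambda: np.arange(0.0, 24.5, 1.0))
    seed: int = 0

    def __post_init__(self):
        self.times = np.asarray(self.times, dtype=float)
        for attr in ("X0", "mu", "Yxs", "Yps", "S0"):
            if getattr(self, attr) <= 0:
                raise ValueError(f"{attr} must be positive")
        if self.noise_sd < 0:
            raise ValueError("noise_sd must be >= 0")


def simulate_batch_culture(
    params: BatchSimParams,
    replicate: str = "r1",
    condition: str = "synthetic",
) -> pd.DataFrame:
    """Simulate one batch growth curve as a tidy frame.

    Columns: ``time_h, dcw_g_l, substrate_g_l, product_g_l, replicate,
    condition``. At ``noise_sd=0`` the curve satisfies the generative
    equations exactly: (X - X0)/Yxs + S = S0 before exhaustion, and
    P = Yps * (S0 - S) throughout. Seed-deterministic.
    """
    p = params
    t = p.times
    X_max = p.X0 + p.Yxs * p.S0  # biomass at substrate exhaustion
    X = np.minimum(p.X0 * np.exp(p.mu * t), X_max)
    S = np.maximum(0.0, p.S0 - (X - p.X0) / p.Yxs)
    P = p.Yps * (p.S0 - S)

    if p.noise_sd > 0:
        rng = np.random.default_rng(p.seed)
        X = X * np.exp(rng.normal(0.0, p.noise_sd, size=t.shape))
        S = S * np.exp(rng.normal(0.0, p.noise_sd, size=t.shape))
        P = P * np.exp(rng.normal(0.0, p.noise_sd, size=t.shape))

    return pd.DataFrame(
        {
            "time_h": t,
            "dcw_g_l": X,
            "substrate_g_l": S,
            "product_g_l": P,
            "replicate": replicate,
            "condition": condition,
        }
    )


#: Peak product titers (g/L) of the engineered strain on whey lactose:
#: the two pyruvate-derived co-products of the 24-h batch.
WHEY_BATCH_TITERS_G_L: dict[str, float] = {"2-KIV": 3.22, "L-valine": 1.40}


def total_product_titer(titers: dict[str, float] | None = None) -> float:
    """Combined product titer (g/L) of a batch, summed over co-products."""
    titers = WHEY_BATCH_TITERS_G_L if titers is None else titers
    return float(sum(titers.values()))


def make_table2_fixture() -> pd.DataFrame:
    """Published 24-h batch endpoints of the engineered producer strain.

    One row per carbon source, with total substrate uptake, final 2-KIV
    titer and the printed biomass yield (from which the biomass increment
    is reconstructed as yxs * delta-substrate). These are the inputs to
    endpoint yield arithmetic; no raw time series is published.
    """
    rows = [
        # condition, substrate uptake g/L, 2-KIV g/L, printed Yx/s g/g, time h
        ("glucose", 10.2, 2.18, 0.04, 24.0),
        ("lactose", 9.0, 2.41, 0.05, 24.0),
        ("whey", 3.9, 3.22, 0.08, 24.0),
    ]
    df = pd.DataFrame(
        rows,
        columns=["condition", "delta_substrate_g_l", "product_g_l", "yxs_printed", "time_h"],
    )
    df["delta_biomass_g_l"] = df["yxs_printed"] * df["delta_substrate_g_l"]
    return df
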