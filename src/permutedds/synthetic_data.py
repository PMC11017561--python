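"""Self-contained synthetic fixtures for the whole pipeline.

Real synergy screens couple a drug-pair table to cell-line omics downloaded
from public databases. This module emulates those inputs at desk scale with
no downloads: drugs are sampled from a packaged vocabulary of valid
small-molecule SMILES, cell lines get i.i.d. Gaussian expression and
Bernoulli(0.1) mutation profiles over synthetic gene symbols, and synergy
labels come from a planted function of the MACCS fingerprints and the
expression profile plus Gaussian noise, standardized to a synergy-score-like
scale (mean 0, sd 20).

The planted label for trio (i, j, c) is

    score = w_drug * <u, f_i + f_j> + w_cell * <v, e_c>
            + w_interaction * <r, f_i * f_j>         (elementwise product)

with u, v, r fixed standard-normal vectors drawn once from the config seed.
The signal is standardized first and noise ``N(0, sigma_label^2)`` is added
after, so ``sigma_label`` is interpretable against the sd-20 score scale.
Labels are symmetric under drug-order swap by construction.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .cell_lines import GenePanel
from .errors import VocabularyExhaustedError
from .synergy_scores import CombinationGrid, DoseResponseParams

# Hand-curated, RDKit-validated small molecules (common drugs, natural
# products and building blocks), each with >= 4 heavy atoms and at least one
# 4-atom torsion path so every fingerprint kind is non-degenerate.
SMILES_VOCABULARY: tuple[str, ...] = (
    "CC(=O)Oc1ccccc1C(=O)O",                        # aspirin
    "Cn1cnc2c1c(=O)n(C)c(=O)n2C",                   # caffeine
    "CC(C)Cc1ccc(cc1)C(C)C(=O)O",                   # ibuprofen
    "CC(=O)Nc1ccc(O)cc1",                           # paracetamol
    "Clc1ccccc1Cl",                                 # 1,2-dichlorobenzene
    "c1ccc2ccccc2c1",                               # naphthalene
    "c1ccc2c(c1)ccc1ccccc21",                       # anthracene (angular)
    "CCOC(=O)c1ccccc1",                             # ethyl benzoate
    "CC(=O)c1ccccc1",                               # acetophenone
    "OCc1ccccc1",                                   # benzyl alcohol
    "Nc1ccc(cc1)S(N)(=O)=O",                        # sulfanilamide
    "OC(=O)c1ccccc1O",                              # salicylic acid
    "COc1ccc(CCN)cc1",                              # 4-methoxyphenethylamine
    "NCCc1ccc(O)c(O)c1",                            # dopamine
    "C1CCNCC1",                                     # piperidine
    "C1CCOC1",                                      # tetrahydrofuran
    "c1ccncc1",                                     # pyridine
    "c1ccc(cc1)c1ccccc1",                           # biphenyl
    "CCCCCC",                                       # hexane
    "CCCCO",                                        # butanol
    "CC(C)(C)c1ccccc1",                             # tert-butylbenzene
    "CCN(CC)CC",                                    # triethylamine
    "OC(=O)CCC(=O)O",                               # succinic acid
    "OC(=O)C=Cc1ccccc1",                            # cinnamic acid
    "CC(N)Cc1ccccc1",                               # amphetamine
    "CN1CCC[C@H]1c1cccnc1",                         # nicotine
    "OCC(O)CO",                                     # glycerol
    "CC(=O)NCCc1c[nH]c2ccc(OC)cc12",                # melatonin
    "CN(C)CCc1c[nH]c2ccccc12",                      # dimethyltryptamine
    "NC(Cc1ccc(O)cc1)C(=O)O",                       # tyrosine
    "NC(Cc1c[nH]c2ccccc12)C(=O)O",                  # tryptophan
    "NC(CC(=O)O)C(=O)O",                            # aspartic acid
    "CSCCC(N)C(=O)O",                               # methionine
    "OC1CCCCC1",                                    # cyclohexanol
    "O=C1CCCCC1",                                   # cyclohexanone
    "CC1CCC(CC1)C(C)C",                             # menthane skeleton
    "CC(=O)OCC",                                    # ethyl acetate
    "CCOCC",                                        # diethyl ether
    "CCCCN",                                        # butylamine
    "ClCCCl",                                       # 1,2-dichloroethane
    "FC(F)(F)c1ccccc1",                             # benzotrifluoride
    "Oc1ccc(cc1)C(c1ccc(O)cc1)(C)C",                # bisphenol A
    "COc1cc(C=O)ccc1O",                             # vanillin
    "O=Cc1ccccc1",                                  # benzaldehyde
    "N#Cc1ccccc1",                                  # benzonitrile
    "O=[N+]([O-])c1ccccc1",                         # nitrobenzene
    "Cc1ccc(C)cc1",                                 # p-xylene
    "Cc1cccc(C)c1C",                                # hemimellitene
    "CCc1ccccc1",                                   # ethylbenzene
    "C=Cc1ccccc1",                                  # styrene
    "OC(c1ccccc1)c1ccccc1",                         # benzhydrol
    "O=C(c1ccccc1)c1ccccc1",                        # benzophenone
    "CC(C)=CCCC(C)=CCO",                            # geraniol
    "CC1=CCC(CC1)C(C)C",                            # limonene-like terpene
    "OC(=O)c1cccnc1",                               # niacin
    "NC(=O)c1cccnc1",                               # nicotinamide
    "Cn1ccnc1",                                     # N-methylimidazole
    "c1ccc2[nH]ccc2c1",                             # indole
    "c1ccc2occc2c1",                                # benzofuran
    "c1ccc2sccc2c1",                                # benzothiophene
    "OCC1OC(O)C(O)C(O)C1O",                         # glucose (pyranose)
    "CC(O)C(=O)O",                                  # lactic acid
)


@dataclass(frozen=True)
class SyntheticConfig:
    """Study conditions for the default synthetic benchmark."""

    n_drugs: int = 20
    n_cells: int = 10
    n_records: int = 500
    g_expr: int = 64
    g_mut: int = 64
    sigma_label: float = 5.0
    seed: int = 0
    effect_weights: tuple[float, float, float] = (1.0, 1.0, 1.0)
    mutation_rate: float = 0.1
    score_sd: float = 20.0

    def __post_init__(self):
        max_records = self.n_cells * self.n_drugs * (self.n_drugs - 1) // 2
        if self.n_records > max_records:
            raise ValueError(
                f"n_records={self.n_records} exceeds the {max_records} distinct trios"
            )
        if self.sigma_label < 0:
            raise ValueError("sigma_label must be >= 0")


def generate_drugs(n: int, seed: int) -> list[tuple[str, str]]:
    """Sample ``n`` distinct (drug_id, SMILES) entries from the vocabulary."""
    if n > len(SMILES_VOCABULARY):
        raise VocabularyExhaustedError(
            f"requested {n} drugs but the vocabulary holds {len(SMILES_VOCABULARY)}"
        )
    rng = np.random.Generator(np.random.PCG64(seed))
    picks = rng.choice(len(SMILES_VOCABULARY), size=n, replace=False)
    return [(f"D{i + 1:03d}", SMILES_VOCABULARY[int(p)]) for i, p in enumerate(picks)]


def generate_cell_panel(
    n_cells: int, g_expr: int, g_mut: int, seed: int, mutation_rate: float = 0.1
) -> tuple[pd.DataFrame, pd.DataFrame, GenePanel]:
    """Gaussian expression and Bernoulli mutation matrices over synthetic genes.

    Returns (expression, mutation) DataFrames indexed by cell id with gene
    symbols ``G0001...`` as columns, plus the resulting :class:`GenePanel`.
    """
    rng = np.random.Generator(np.random.PCG64(seed))
    cells = [f"CL{i + 1:03d}" for i in range(n_cells)]
    expr_genes = [f"G{i + 1:04d}" for i in range(g_expr)]
    mut_genes = [f"M{i + 1:04d}" for i in range(g_mut)]
    expr = pd.DataFrame(
        rng.normal(size=(n_cells, g_expr)), index=cells, columns=expr_genes
    )
    mut = pd.DataFrame(
        (rng.random(size=(n_cells, g_mut)) < mutation_rate).astype(float),
        index=cells,
        columns=mut_genes,
    )
    panel = GenePanel(expression_genes=tuple(expr_genes), mutation_genes=tuple(mut_genes))
    return expr, mut, panel


def generate_trios(
    n_records: int, drug_ids: list[str], cell_ids: list[str], seed: int
) -> list[tuple[str, str, str]]:
    """Sample distinct (drug_a, drug_b, cell) trios, unordered in the pair."""
    pairs = [
        (drug_ids[i], drug_ids[j])
        for i in range(len(drug_ids))
        for j in range(i + 1, len(drug_ids))
    ]
    combos = [(a, b, c) for (a, b) in pairs for c in cell_ids]
    if n_records > len(combos):
        raise ValueError(f"cannot draw {n_records} distinct trios from {len(combos)}")
    rng = np.random.Generator(np.random.PCG64(seed))
    picks = rng.choice(len(combos), size=n_records, replace=False)
    return [combos[int(p)] for p in picks]


def _maccs_vector(entry) -> np.ndarray:
    """Accept either a (hashtt, map4, maccs) triple or a bare vector."""
    if isinstance(entry, tuple):
        entry = entry[2]
    values = getattr(entry, "values", entry)
    return np.asarray(values, dtype=float)


def generate_labels(
    trios: list[tuple[str, str, str]],
    fingerprints: dict,
    expression: pd.DataFrame,
    cfg: SyntheticConfig,
) -> np.ndarray:
    """Planted synergy labels for a list of trios.

    ``fingerprints`` maps drug id to its fingerprint triple (only MACCS is
    used, keeping the oracle independent of the configurable HashTT / MAP4
    lengths). The noiseless signal is standardized to mean 0 / sd
    ``score_sd`` before ``N(0, sigma_label^2)`` noise is added.
    """
    rng = np.random.Generator(np.random.PCG64(cfg.seed))
    maccs = {d: _maccs_vector(v) for d, v in fingerprints.items()}
    n_fp = len(next(iter(maccs.values())))
    u = rng.normal(size=n_fp)
    v = rng.normal(size=expression.shape[1])
    r = rng.normal(size=n_fp)
    w_drug, w_cell, w_inter = cfg.effect_weights
    signal = np.empty(len(trios))
    for idx, (a, b, c) in enumerate(trios):
        fa, fb = maccs[a], maccs[b]
        e_c = expression.loc[c].to_numpy()
        signal[idx] = (
            w_drug * np.dot(u, fa + fb)
            + w_cell * np.dot(v, e_c)
            + w_inter * np.dot(r, fa * fb)
        )
    sd = signal.std()
    if sd > 0:
        signal = (signal - signal.mean()) / sd * cfg.score_sd
    noise = rng.normal(scale=cfg.sigma_label, size=len(trios)) if cfg.sigma_label else 0.0
    return signal + noise


def generate_dose_grids(
    n: int, seed: int
) -> list[tuple[CombinationGrid, DoseResponseParams]]:
    """Random dose-response parameter sets and 3x3..5x5 combination grids."""
    rng = np.random.Generator(np.random.PCG64(seed))
    out = []
    for _ in range(n):
        r_min = rng.uniform(0.0, 30.0)
        r_max = r_min + rng.uniform(10.0, 100.0)  # keeps r_min < r_max
        params = DoseResponseParams(
            r_min=r_min,
            r_max=r_max,
            m=float(np.exp(rng.uniform(np.log(0.1), np.log(10.0)))),
            lam=float(rng.uniform(0.5, 4.0)),
        )
        rows, cols = rng.integers(3, 6, size=2)
        grid = CombinationGrid(
            observed=rng.uniform(0.0, 1.2, size=(rows, cols)),
            expected=rng.uniform(0.0, 1.2, size=(rows, cols)),
        )
        out.append((grid, params))
    return out
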