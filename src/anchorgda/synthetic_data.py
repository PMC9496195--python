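"""Synthetic expression datasets with planted, known ground truth.

The generator emulates the structure the pipeline is designed to detect in
a two-group (control vs disease) expression study:

* an anchor gene drawn N(0, 1) in controls and N(delta, 1) in cases, so its
  theoretical two-group AUC is Phi(delta / sqrt(2));
* a block of genes correlated to the anchor within the case group at a
  target Pearson rho_pos (g = rho * anchor_z + sqrt(1 - rho^2) * noise) and
  a block anti-correlated at -rho_neg — the screen's co-expression signal is
  planted in the cases only, mirroring a within-patient stratification;
* independent standard-normal background genes everywhere else;
* gene signatures drawn preferentially from a named block, the remainder
  from background, so signature enrichment of the screened lists has a known
  expected outcome (the "microglia-like in GSPC, neuron-like in GSNC"
  dichotomy at the scale where it is literally testable).

Defaults mirror the motivating study's conditions: 10 control + 13 case
samples, anchor shift delta = 1.1 sd (theoretical AUC ~ 0.78, the reported
discrimination level of the anchor marker), correlation blocks at
rho = +/-0.8, and a fixed annotation universe of 20,203 genes.

A single global seed drives a named substream per component, so adding a
later stage never perturbs earlier draws.
"""

from __future__ import annotations

import json
import logging
from dataclasses import asdict, dataclass
from pathlib import Path

import numpy as np
import pandas as pd
from scipy import stats

from anchorgda.core_io import (
    DEFAULT_UNIVERSE_SIZE,
    ExpressionMatrix,
    GeneSignature,
    SignatureCollection,
)
from anchorgda.drug_ranking import signature_similarity
from statsmodels.stats.multitest import multipletests

_STREAMS = ("anchor", "block_pos", "block_neg", "background", "signatures", "perturbations")


@dataclass(frozen=True)
class SignatureSpec:
    """Recipe for one synthetic signature: size D genes, ``fraction`` of them
    sampled from the named planted block ('pos'/'neg'), the rest background."""

    name: str
    size: int
    block: str  # "pos" or "neg"
    fraction: float
    category: str = "process"

    def __post_init__(self) -> None:
        if self.block not in ("pos", "neg"):
            raise ValueError("block must be 'pos' or 'neg'")
        if not 0 <= self.fraction <= 1:
            raise ValueError("fraction must lie in [0, 1]")
        if self.size <= 0:
            raise ValueError("signature size must be positive")


@dataclass(frozen=True)
class SimulationConfig:
    n_neg: int = 10
    n_pos: int = 13
    n_genes: int = 2000
    anchor_shift: float = 1.1
    block_pos_size: int = 300
    block_neg_size: int = 400
    rho_pos: float = 0.8
    rho_neg: float = 0.8
    signature_specs: tuple[SignatureSpec, ...] = (
        SignatureSpec("microglia_like", 120, "pos", 0.6, category="immune"),
        SignatureSpec("neuron_like", 900, "neg", 0.5, category="neural"),
    )
    universe_size: int = DEFAULT_UNIVERSE_SIZE
    anchor_name: str = "GJA1"
    neg_group: str = "NDC"
    pos_group: str = "ALS"
    seed: int = 0

    def __post_init__(self) -> None:
        if self.block_pos_size + self.block_neg_size + 1 > self.n_genes:
            raise ValueError("planted blocks plus the anchor exceed n_genes")
        if not (0 < self.rho_pos < 1 and 0 < self.rho_neg < 1):
            raise ValueError("target correlations must lie in (0, 1)")
        if self.n_neg < 2 or self.n_pos < 2:
            raise ValueError("each group needs >=2 samples")
        if self.universe_size < self.n_genes:
            raise ValueError("universe_size must cover the simulated genes")


@dataclass
class GroundTruth:
    """Planted structure of one simulated dataset."""

    block_membership: dict[str, str]        # gene -> anchor/pos/neg/background
    intended_rho: dict[str, float]          # planted genes -> target r
    signature_provenance: dict[str, dict[str, str]]  # signature -> gene -> source
    theoretical_auc: float                  # Phi(delta / sqrt(2))

    def block_genes(self, block: str) -> list[str]:
        return [g for g, b in self.block_membership.items() if b == block]

    def to_json(self, path: str | Path) -> None:
        with open(path, "w", encoding="utf-8") as fh:
            json.dump(asdict(self), fh, indent=1)


def _streams(seed: int) -> dict[str, np.random.Generator]:
    children = np.random.SeedSequence(seed).spawn(len(_STREAMS))
    return {name: np.random.default_rng(child) for name, child in zip(_STREAMS, children)}


def _standardize(v: np.ndarray) -> np.ndarray:
    return (v - v.mean()) / v.std()


def generate_dataset(
    config: SimulationConfig,
) -> tuple[ExpressionMatrix, SignatureCollection, GroundTruth]:
    """Simulate an expression matrix, signature collection and ground truth.

    Bit-identical for a given config (including seed).
    """
    rng = _streams(config.seed)
    n_neg, n_pos = config.n_neg, config.n_pos
    n_bg = config.n_genes - 1 - config.block_pos_size - config.block_neg_size

    anchor_neg = rng["anchor"].normal(0.0, 1.0, n_neg)
    anchor_pos = rng["anchor"].normal(config.anchor_shift, 1.0, n_pos)
    anchor_z = _standardize(anchor_pos)  # within-case standardized anchor

    def correlated_block(gen, size: int, rho: float) -> np.ndarray:
        ctrl = gen.normal(0.0, 1.0, (size, n_neg))
        noise = gen.normal(0.0, 1.0, (size, n_pos))
        case = rho * anchor_z + np.sqrt(1.0 - rho**2) * noise
        return np.hstack([ctrl, case])

    pos_block = correlated_block(rng["block_pos"], config.block_pos_size, config.rho_pos)
    neg_block = correlated_block(rng["block_neg"], config.block_neg_size, -config.rho_neg)
    background = rng["background"].normal(0.0, 1.0, (n_bg, n_neg + n_pos))

    pos_names = [f"POS{i:04d}" for i in range(1, config.block_pos_size + 1)]
    neg_names = [f"NEG{i:04d}" for i in range(1, config.block_neg_size + 1)]
    bg_names = [f"BG{i:05d}" for i in range(1, n_bg + 1)]
    genes = [config.anchor_name, *pos_names, *neg_names, *bg_names]
    data = np.vstack([np.concatenate([anchor_neg, anchor_pos])[None, :],
                      pos_block, neg_block, background])

    samples = [f"{config.neg_group}_{i:02d}" for i in range(1, n_neg + 1)] + [
        f"{config.pos_group}_{i:02d}" for i in range(1, n_pos + 1)
    ]
    labels = {s: (config.neg_group if i < n_neg else config.pos_group)
              for i, s in enumerate(samples)}
    matrix = ExpressionMatrix(
        values=pd.DataFrame(data, index=genes, columns=samples), group_labels=labels
    )

    block_pool = {"pos": pos_names, "neg": neg_names}
    sig_rng = rng["signatures"]
    signatures, provenance = [], {}
    for spec in config.signature_specs:
        pool = block_pool[spec.block]
        k = min(int(round(spec.fraction * spec.size)), len(pool))
        n_rest = spec.size - k
        if n_rest > len(bg_names):
            # small simulations cannot honour the full requested size; cap the
            # background draw rather than fail, and say so
            logging.getLogger(__name__).warning(
                "signature %s capped at %d background genes (%d requested)",
                spec.name, len(bg_names), n_rest,
            )
            n_rest = len(bg_names)
        from_block = list(sig_rng.choice(pool, size=k, replace=False))
        from_bg = list(sig_rng.choice(bg_names, size=n_rest, replace=False))
        provenance[spec.name] = {g: spec.block for g in from_block}
        provenance[spec.name].update({g: "background" for g in from_bg})
        signatures.append(
            GeneSignature(
                name=spec.name,
                category=spec.category,
                source_tag="synthetic",
                genes=frozenset(from_block + from_bg),
            )
        )
    collection = SignatureCollection(signatures=signatures,
                                     universe_size=config.universe_size)

    membership = {config.anchor_name: "anchor"}
    membership.update({g: "pos" for g in pos_names})
    membership.update({g: "neg" for g in neg_names})
    membership.update({g: "background" for g in bg_names})
    intended = {config.anchor_name: 1.0}
    intended.update({g: config.rho_pos for g in pos_names})
    intended.update({g: -config.rho_neg for g in neg_names})
    truth = GroundTruth(
        block_membership=membership,
        intended_rho=intended,
        signature_provenance=provenance,
        theoretical_auc=float(stats.norm.cdf(config.anchor_shift / np.sqrt(2.0))),
    )
    return matrix, collection, truth


def generate_perturbation_table(
    n_drugs: int,
    n_true_reversers: int,
    config: SimulationConfig | None = None,
    seed: int = 0,
    query_size: int = 100,
    corruption: float = 0.0,
) -> tuple[pd.DataFrame, dict]:
    """Simulate a drug-perturbation table with known reversers.

    The query signature's up/down sets are drawn from the config's positive
    and negative planted blocks. A true reverser swaps the query's up and
    down sets, with a ``corruption`` fraction of its genes replaced by random
    symbols; decoys are random gene sets of the same sizes drawn from the
    whole universe. similarity/z/p come from
    :func:`anchorgda.drug_ranking.signature_similarity`; q is BH across drugs.

    Returns the table (drug, similarity, zscore, pvalue, qvalue, moa) and a
    truth dict naming the planted reversers and the query sets.
    """
    if n_true_reversers > n_drugs:
        raise ValueError("n_true_reversers cannot exceed n_drugs")
    config = config or SimulationConfig()
    rng = np.random.default_rng(np.random.SeedSequence([seed, config.seed]))

    pos_names = [f"POS{i:04d}" for i in range(1, config.block_pos_size + 1)]
    neg_names = [f"NEG{i:04d}" for i in range(1, config.block_neg_size + 1)]
    universe = [f"U{i:05d}" for i in range(1, config.universe_size + 1)]

    k_up = min(query_size, len(pos_names))
    k_down = min(query_size, len(neg_names))
    query_up = list(rng.choice(pos_names, size=k_up, replace=False))
    query_down = list(rng.choice(neg_names, size=k_down, replace=False))

    def corrupt(genes: list[str]) -> list[str]:
        n_swap = int(round(corruption * len(genes)))
        if n_swap == 0:
            return list(genes)
        keep = list(rng.choice(genes, size=len(genes) - n_swap, replace=False))
        filler = list(rng.choice(universe, size=n_swap, replace=False))
        return keep + filler

    rows, reversers = [], []
    for i in range(n_drugs):
        name = f"drug_{i + 1:03d}"
        if i < n_true_reversers:
            pert_up, pert_down = corrupt(query_down), corrupt(query_up)
            moa = "planted_reverser"
            reversers.append(name)
        else:
            draw = rng.choice(universe, size=k_up + k_down, replace=False)
            pert_up, pert_down = list(draw[:k_up]), list(draw[k_up:])
            moa = "decoy"
        sim, z, p = signature_similarity(
            query_up, query_down, pert_up, pert_down, N=config.universe_size
        )
        rows.append({"drug": name, "similarity": sim, "zscore": z,
                     "pvalue": p, "moa": moa})

    table = pd.DataFrame(rows)
    _, qvals, _, _ = multipletests(table["pvalue"], method="fdr_bh")
    table["qvalue"] = qvals
    table = table[["drug", "similarity", "zscore", "pvalue", "qvalue", "moa"]]
    truth = {
        "reversers": reversers,
        "query_up": query_up,
        "query_down": query_down,
        "corruption": corruption,
    }
    return table, truth
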