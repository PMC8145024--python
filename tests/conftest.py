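"""Shared fixtures and independent oracles for the test suite."""

from __future__ import annotations

import numpy as np
import pytest

from iugrnet.hybridization import _CODE, _PAIR_INDEX, load_energy_model
from iugrnet.synthetic import SimConfig, simulate_all


def pair_code(a: str, b: str) -> int:
    return int(_PAIR_INDEX[_CODE[a], _CODE[b]])


def oracle_duplex_mfe(mir: str, win: str, model, helix=(2, 7)):
    """Plain recursive enumeration of all legal duplex pairings.

    Independent of the vectorized dynamic program: walks every antiparallel
    pairing compatible with the helix constraint and the model's loop caps,
    summing energies directly from the definition.  Returns the minimum
    energy or None when the helix constraint cannot be satisfied.
    """
    L, W = len(mir), len(win)
    h0, h1 = helix[0] - 1, helix[1] - 1
    span = h1 - h0

    def ext(i, j):
        out = 0.0
        for i2 in range(i + 1, L):
            gm = i2 - i - 1
            for j2 in range(j - 1, -1, -1):
                gt = j - j2 - 1
                if pair_code(mir[i2], win[j2]) < 0:
                    continue
                if gm == 0 and gt == 0:
                    c = model.stack[pair_code(mir[i], win[j]), pair_code(mir[i2], win[j2])]
                elif gm == 0 or gt == 0:
                    if gm + gt > model.max_bulge:
                        continue
                    c = model.bulge[gm + gt]
                else:
                    if gm + gt > model.max_internal:
                        continue
                    c = model.internal[gm + gt]
                v = c + ext(i2, j2)
                out = min(out, v)
        return out

    best = None
    for j6 in range(0, W - span):
        codes = [pair_code(mir[i], win[j6 + h1 - i]) for i in range(h0, h1 + 1)]
        if any(c < 0 for c in codes):
            continue
        if not model.wobble_in_helix and any(c >= 4 for c in codes):
            continue
        e = model.duplex_init
        for i in range(h0, h1):
            e += model.stack[
                pair_code(mir[i], win[j6 + h1 - i]),
                pair_code(mir[i + 1], win[j6 + h1 - i - 1]),
            ]
        pre = 0.0
        if h0 == 1:
            jt = j6 + span
            if jt + 1 < W and pair_code(mir[0], win[jt + 1]) >= 0:
                pre = min(
                    pre,
                    model.stack[
                        pair_code(mir[0], win[jt + 1]), pair_code(mir[1], win[jt])
                    ],
                )
            for g in range(1, model.max_bulge + 1):
                if jt + 1 + g < W and pair_code(mir[0], win[jt + 1 + g]) >= 0:
                    pre = min(pre, model.bulge[g])
        tot = e + pre + ext(h1, j6)
        best = tot if best is None else min(best, tot)
    return best


def random_duplex_instance(rng, bias_seed_site: bool = True):
    """A small (miRNA, window) instance, usually carrying a seed match."""
    from iugrnet.hybridization import reverse_complement_rna

    bases = np.array(list("ACGU"))
    L = int(rng.integers(8, 13))
    W = int(rng.integers(10, 26))
    mir = "".join(rng.choice(bases, L))
    win = "".join(rng.choice(bases, W))
    if bias_seed_site and rng.random() < 0.7:
        site = reverse_complement_rna(mir[1:7])
        pos = int(rng.integers(0, W - 6 + 1))
        win = win[:pos] + site + win[pos + 6 :]
    return mir, win


@pytest.fixture(scope="session")
def model():
    return load_energy_model()


@pytest.fixture(scope="session")
def small_sim_config():
    """Scaled-down synthetic study for unit tests (study-strength effects)."""
    return SimConfig(
        seed=11,
        n_dams=6,
        litter_size_range=(10, 12),
        n_per_group=8,
        n_mirna_probes=40,
        n_mrna_probes=120,
        n_true_de_mirna=8,
        n_true_de_mrna=24,
        n_planted_pairs=10,
        utr3_len_range=(300, 2200),
        utr5_len_range=(100, 200),
        cds_len_range=(500, 2100),
        n_gene_sets=12,
        n_enriched_sets=2,
    )


@pytest.fixture(scope="session")
def small_bundle(small_sim_config):
    return simulate_all(small_sim_config)


@pytest.fixture(scope="session")
def table1_cohort():
    from iugrnet.phenotype import load_example_cohort

    return load_example_cohort()
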