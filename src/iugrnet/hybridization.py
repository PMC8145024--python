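"""miRNA target prediction by intermolecular duplex minimum free energy.

Transcript regions (3'UTR, 5'UTR, CDS) are fragmented into 2000-nt windows
overlapping by 50 nt and scanned with a dynamic program over *intermolecular*
duplex structures only: no intramolecular pairs form in either strand.  A
structure is a set of antiparallel miRNA:target base pairs (Watson-Crick and
G:U wobble); its energy is the duplex initiation term plus nearest-neighbor
stacking energies for adjacent pairs and length-dependent bulge/internal-loop
penalties for interrupted helices.  Isolated pair formation itself carries no
energy term, matching nearest-neighbor convention.

A seed ("helix") constraint requires miRNA positions 2-7 (1-based from the
5' end) to be paired with consecutive target bases; wobble pairs are allowed
inside the forced helix by default (the constraint forces pairedness, not
pair identity), configurable via the energy-model file.

A gene is called a target when its single lowest-MFE site across all regions
is strictly below the threshold (default -25 kcal/mol).
"""

from __future__ import annotations

from dataclasses import dataclass
from importlib import resources

import numpy as np
import yaml

__all__ = [
    "EnergyModel",
    "TranscriptRegion",
    "Fragment",
    "DuplexHit",
    "WindowHit",
    "load_energy_model",
    "transcribe",
    "reverse_complement_rna",
    "fragment_sequence",
    "duplex_mfe",
    "scan_target",
    "predict_targets",
]

_CODE = {"A": 0, "C": 1, "G": 2, "U": 3}
_PAIR_NAMES = ("AU", "UA", "CG", "GC", "GU", "UG")
_PAIR_INDEX = np.full((4, 4), -1, dtype=int)
for _k, _pn in enumerate(_PAIR_NAMES):
    _PAIR_INDEX[_CODE[_pn[0]], _CODE[_pn[1]]] = _k
_WC = np.array([True, True, True, True, False, False])  # per pair code
_REV = {"AU": "UA", "UA": "AU", "CG": "GC", "GC": "CG", "GU": "UG", "UG": "GU"}

REGIONS = ("3UTR", "5UTR", "CDS")
_INF = np.inf


def transcribe(seq: str) -> str:
    """DNA or RNA input to upper-case RNA."""
    return seq.upper().replace("T", "U")


def reverse_complement_rna(seq: str) -> str:
    comp = {"A": "U", "U": "A", "G": "C", "C": "G"}
    return "".join(comp[b] for b in reversed(transcribe(seq)))


def _encode(seq: str, what: str) -> np.ndarray:
    seq = transcribe(seq)
    if set(seq) - set(_CODE):
        raise ValueError(f"{what} contains non-RNA characters: {seq!r}")
    return np.array([_CODE[b] for b in seq], dtype=int)


@dataclass(frozen=True)
class TranscriptRegion:
    gene_id: str
    region: str  # 3UTR | 5UTR | CDS
    sequence: str  # DNA or RNA; transcribed on use

    def __post_init__(self) -> None:
        if self.region not in REGIONS:
            raise ValueError(f"unknown region class {self.region!r}")
        if len(self.sequence) < 1:
            raise ValueError(f"{self.gene_id}/{self.region}: empty sequence")


@dataclass(frozen=True)
class Fragment:
    gene_id: str
    region: str
    index: int
    start: int  # 0-based half-open offsets into the region sequence
    end: int


@dataclass(frozen=True)
class WindowHit:
    """Best duplex within one target window (coordinates window-local)."""

    mfe: float
    target_start: int
    target_end: int
    pairing: str
    n_pairs: int


@dataclass(frozen=True)
class DuplexHit:
    """One miRNA:gene hybridization site, region coordinates (0-based half-open)."""

    mirna_id: str
    gene_id: str
    region: str
    fragment_index: int
    target_start: int
    target_end: int
    mfe: float
    pairing: str


class EnergyModel:
    """Nearest-neighbor stack table plus loop penalties for duplex scoring."""

    def __init__(
        self,
        stacks: dict,
        bulge: dict,
        internal: dict,
        duplex_init: float,
        wobble_in_helix: bool = True,
        version: int = 0,
    ):
        self.version = version
        self.duplex_init = float(duplex_init)
        self.wobble_in_helix = bool(wobble_in_helix)
        table = np.full((6, 6), _INF)
        for key, val in stacks.items():
            p, q = key.split(".")
            table[_PAIR_NAMES.index(p), _PAIR_NAMES.index(q)] = float(val)
        for p in _PAIR_NAMES:
            for q in _PAIR_NAMES:
                a = table[_PAIR_NAMES.index(p), _PAIR_NAMES.index(q)]
                b = table[_PAIR_NAMES.index(_REV[q]), _PAIR_NAMES.index(_REV[p])]
                if not np.isfinite(a) or abs(a - b) > 1e-9:
                    raise ValueError(
                        f"stack table incomplete or asymmetric at {p}.{q}"
                    )
                if _WC[_PAIR_NAMES.index(p)] and _WC[_PAIR_NAMES.index(q)] and a > 0:
                    raise ValueError(f"WC/WC stack {p}.{q} must be <= 0")
        self.stack = table
        self.max_bulge = max(bulge)
        self.bulge = np.full(self.max_bulge + 1, _INF)
        for g, v in bulge.items():
            if v < 0:
                raise ValueError("bulge penalties must be >= 0")
            self.bulge[int(g)] = float(v)
        if np.any(np.diff(self.bulge[1:]) < 0):
            raise ValueError("bulge penalties must be nondecreasing")
        self.max_internal = max(internal)
        self.internal = np.full(self.max_internal + 1, _INF)
        for g, v in internal.items():
            if v < 0:
                raise ValueError("internal-loop penalties must be >= 0")
            self.internal[int(g)] = float(v)
        if np.any(np.diff(self.internal[2:]) < 0):
            raise ValueError("internal-loop penalties must be nondecreasing")


def load_energy_model(path=None) -> EnergyModel:
    """Load an energy model from YAML (packaged v1 table by default)."""
    if path is None:
        src = resources.files("iugrnet.data").joinpath("rna_duplex_energies_v1.yaml")
        raw = yaml.safe_load(src.read_text())
    else:
        with open(path) as fh:
            raw = yaml.safe_load(fh)
    return EnergyModel(
        stacks=raw["stacks"],
        bulge=raw["bulge"],
        internal=raw["internal"],
        duplex_init=raw["duplex_init"],
        wobble_in_helix=raw.get("wobble_in_helix", True),
        version=raw.get("version", 0),
    )


def fragment_sequence(
    sequence: str,
    fragment_len: int = 2000,
    overlap: int = 50,
    gene_id: str = "",
    region: str = "3UTR",
):
    """Cut a region into overlapping windows (step = fragment_len - overlap).

    The final fragment ends at the sequence length and may be shorter; the
    union of fragments covers the whole sequence.
    """
    if overlap < 0 or overlap >= fragment_len:
        raise ValueError("need fragment_len > overlap >= 0")
    L = len(sequence)
    if L < 1:
        raise ValueError("cannot fragment an empty sequence")
    step = fragment_len - overlap
    frags, start, idx = [], 0, 0
    while True:
        end = min(start + fragment_len, L)
        frags.append(Fragment(gene_id, region, idx, start, end))
        if end >= L:
            break
        start += step
        idx += 1
    return frags


def _shift(v: np.ndarray, dj: int) -> np.ndarray:
    """out[j] = v[j - dj] (positions without a predecessor become +inf)."""
    out = np.full_like(v, _INF)
    if dj < v.shape[0]:
        out[dj:] = v[: v.shape[0] - dj]
    return out


def duplex_mfe(
    mirna_seq: str,
    target_window: str,
    model: EnergyModel,
    helix: tuple = (2, 7),
) -> WindowHit | None:
    """Minimum-free-energy duplex between a miRNA and one target window.

    Dynamic program over all antiparallel intermolecular pairings in which
    miRNA positions ``helix[0]..helix[1]`` (1-based from the miRNA 5' end)
    pair with consecutive target bases.  Returns the best structure (ties
    broken toward the 5'-most target window position) or None when the
    constraint cannot be satisfied.
    """
    m = _encode(mirna_seq, "miRNA")
    t = _encode(target_window, "target window")
    L, W = m.shape[0], t.shape[0]
    h0, h1 = helix[0] - 1, helix[1] - 1
    if h1 <= h0:
        raise ValueError("helix end must exceed helix start")
    if h0 not in (0, 1):
        raise NotImplementedError("helix constraint must start at miRNA base 1 or 2")
    if L < 7 or L < h1 + 1:
        raise ValueError("miRNA shorter than the constrained helix")
    span = h1 - h0  # target distance covered by the forced helix
    if W < h1 - h0 + 1:
        return None

    P = _PAIR_INDEX[m[:, None], t[None, :]]  # L x W pair codes, -1 disallowed
    allowed = P >= 0
    stack6 = np.vstack([model.stack, np.full((1, 6), _INF)])
    stack7 = np.hstack([stack6, np.full((7, 1), _INF)])  # index -1 -> +inf

    def stack_row(i: int) -> np.ndarray:
        """S[j] = stacking energy of step pair(i, j) over pair(i+1, j-1)."""
        s = np.full(W, _INF)
        if i + 1 < L and W >= 2:
            s[1:] = stack7[P[i, 1:], P[i + 1, :-1]]
        return s

    # --- 3' extension: T[i][j] = best additional energy past last pair (i, j)
    max_di = 1 + max(model.max_bulge, model.max_internal - 1)
    T = np.full((L, W), _INF)
    for i in range(L - 1, h1 - 1, -1):
        best = np.zeros(W)  # stopping is always available
        if i + 1 < L:
            s = stack_row(i)
            best = np.minimum(best, s + _shift(T[i + 1], 1))
            for g in range(1, model.max_bulge + 1):  # target-side bulge
                best = np.minimum(best, model.bulge[g] + _shift(T[i + 1], 1 + g))
        for di in range(2, min(max_di, L - 1 - i) + 1):
            gm = di - 1
            if gm <= model.max_bulge:  # miRNA-side bulge
                best = np.minimum(best, model.bulge[gm] + _shift(T[i + di], 1))
            for gt in range(1, model.max_internal - gm + 1):
                best = np.minimum(
                    best, model.internal[gm + gt] + _shift(T[i + di], 1 + gt)
                )
        best[~allowed[i]] = _INF
        T[i] = best

    # --- forced helix: miRNA index i in [h0, h1] pairs target j6 + (h1 - i)
    n6 = W - span
    hel_ok = np.ones(n6, dtype=bool)
    hel_e = np.zeros(n6)
    for i in range(h0, h1 + 1):
        off = h1 - i
        ok = allowed[i, off : off + n6]
        if not model.wobble_in_helix:
            ok = ok & _WC[np.clip(P[i, off : off + n6], 0, 5)]
        hel_ok &= ok
    # stacking inside the helix, vectorized over j6
    for i in range(h0, h1):
        off = h1 - i  # pair (i, j6+off); step uses S[i, j6+off]
        s = stack_row(i)
        hel_e = hel_e + s[off : off + n6]

    # --- optional single 5' base (miRNA index 0) when the helix starts at 2
    pre = np.zeros(n6)
    if h0 == 1:
        jt = np.arange(n6) + span  # target index paired with miRNA base 2
        s0 = stack_row(0)
        opt = np.zeros(n6)
        cand = np.full(n6, _INF)
        idx = jt + 1
        okj = idx < W
        cand[okj] = s0[idx[okj]]
        opt = np.minimum(opt, cand)
        for g in range(1, model.max_bulge + 1):
            idx = jt + 1 + g
            okj = idx < W
            cand = np.full(n6, _INF)
            cand[okj] = np.where(allowed[0, idx[okj]], model.bulge[g], _INF)
            opt = np.minimum(opt, cand)
        pre = opt

    total = model.duplex_init + pre + hel_e + T[h1, :n6]
    total[~hel_ok] = _INF
    if not np.any(np.isfinite(total)):
        return None
    j6 = int(np.argmin(total))
    mfe = float(total[j6])

    pairs = _traceback(model, P, allowed, T, stack_row, h0, h1, span, j6, W, L)
    tmin = min(j for _, j in pairs)
    tmax = max(j for _, j in pairs)
    paired_m = {i for i, _ in pairs}
    paired_t = {j for _, j in pairs}
    m_struct = "".join("(" if i in paired_m else "." for i in range(L))
    t_struct = "".join(
        ")" if j in paired_t else "." for j in range(tmin, tmax + 1)
    )
    return WindowHit(mfe, tmin, tmax + 1, m_struct + "&" + t_struct, len(pairs))


def _traceback(model, P, allowed, T, stack_row, h0, h1, span, j6, W, L):
    tol = 1e-9
    pairs = [(i, j6 + (h1 - i)) for i in range(h0, h1 + 1)]
    # 5' side
    if h0 == 1:
        jt = j6 + span
        target = 0.0
        s0 = stack_row(0)
        best = 0.0
        choice = None
        if jt + 1 < W and s0[jt + 1] < best - tol:
            best, choice = s0[jt + 1], jt + 1
        for g in range(1, model.max_bulge + 1):
            if jt + 1 + g < W and allowed[0, jt + 1 + g]:
                if model.bulge[g] < best - tol:
                    best, choice = model.bulge[g], jt + 1 + g
        if choice is not None:
            pairs.insert(0, (0, choice))
    # 3' side: replay the T recurrence greedily
    i, j = h1, j6
    max_di = 1 + max(model.max_bulge, model.max_internal - 1)
    while T[i, j] < -tol or T[i, j] > tol:
        val = T[i, j]
        nxt = None
        if i + 1 < L and j - 1 >= 0:
            s = stack_row(i)
            if abs(s[j] + T[i + 1, j - 1] - val) <= tol:
                nxt = (i + 1, j - 1)
            if nxt is None:
                for g in range(1, model.max_bulge + 1):
                    if j - 1 - g >= 0 and abs(
                        model.bulge[g] + T[i + 1, j - 1 - g] - val
                    ) <= tol:
                        nxt = (i + 1, j - 1 - g)
                        break
        if nxt is None:
            for di in range(2, min(max_di, L - 1 - i) + 1):
                gm = di - 1
                if gm <= model.max_bulge and j - 1 >= 0 and abs(
                    model.bulge[gm] + T[i + di, j - 1] - val
                ) <= tol:
                    nxt = (i + di, j - 1)
                    break
                for gt in range(1, model.max_internal - gm + 1):
                    if j - 1 - gt >= 0 and abs(
                        model.internal[gm + gt] + T[i + di, j - 1 - gt] - val
                    ) <= tol:
                        nxt = (i + di, j - 1 - gt)
                        break
                if nxt is not None:
                    break
        if nxt is None:  # numerically safe stop
            break
        pairs.append(nxt)
        i, j = nxt
    return pairs


def scan_target(
    mirna_id: str,
    mirna_seq: str,
    regions,
    model: EnergyModel,
    mfe_threshold: float = -25.0,
    fragment_len: int = 2000,
    overlap: int = 50,
    helix: tuple = (2, 7),
) -> DuplexHit | None:
    """Best duplex hit for one gene across all its region fragments.

    Evaluates every fragment of every supplied region, maps window hits back
    to region coordinates, deduplicates sites shared by overlapping
    fragments by (region, target_start), and keeps the single lowest-MFE
    site for the gene.  The hit is reported only when MFE < threshold
    (strict).
    """
    regions = list(regions)
    if not regions:
        raise ValueError(f"no sequence available for gene (miRNA {mirna_id})")
    gene_id = regions[0].gene_id
    L = len(mirna_seq)
    seen = {}
    for reg in regions:
        seq = transcribe(reg.sequence)
        for frag in fragment_sequence(
            seq, fragment_len, overlap, gene_id=reg.gene_id, region=reg.region
        ):
            window = seq[frag.start : frag.end]
            if len(window) < L:
                continue
            hit = duplex_mfe(mirna_seq, window, model, helix=helix)
            if hit is None:
                continue
            key = (reg.region, frag.start + hit.target_start)
            cand = DuplexHit(
                mirna_id,
                reg.gene_id,
                reg.region,
                frag.index,
                frag.start + hit.target_start,
                frag.start + hit.target_end,
                hit.mfe,
                hit.pairing,
            )
            if key not in seen or cand.mfe < seen[key].mfe:
                seen[key] = cand
    if not seen:
        return None
    best = min(
        seen.values(), key=lambda h: (h.mfe, h.region, h.target_start, h.fragment_index)
    )
    return best if best.mfe < mfe_threshold else None


def predict_targets(
    mirnas,
    gene_regions: dict,
    gene_directions: dict,
    model: EnergyModel,
    mfe_threshold: float = -25.0,
    fragment_len: int = 2000,
    overlap: int = 50,
    helix: tuple = (2, 7),
):
    """Scan opposite-direction (miRNA, gene) combinations; return a hit table.

    ``mirnas`` is an iterable of (mirna_id, sequence, direction) or a
    DataFrame with those columns; ``gene_directions`` maps gene_id to
    "up"/"down".  Two passes mirror the study design: upregulated miRNAs are
    scanned against downregulated genes and vice versa.
    """
    import pandas as pd

    if hasattr(mirnas, "itertuples"):
        mirnas = [
            (r.mirna_id, r.sequence, r.direction) for r in mirnas.itertuples(index=False)
        ]
    rows = []
    opposite = {"up": "down", "down": "up"}
    for mirna_id, seq, direction in mirnas:
        if direction not in opposite:
            continue
        want = opposite[direction]
        for gene_id in sorted(g for g, d in gene_directions.items() if d == want):
            regions = gene_regions.get(gene_id)
            if not regions:
                raise ValueError(f"no sequence for gene {gene_id}")
            hit = scan_target(
                mirna_id,
                seq,
                regions,
                model,
                mfe_threshold=mfe_threshold,
                fragment_len=fragment_len,
                overlap=overlap,
                helix=helix,
            )
            if hit is None:
                continue
            rows.append(
                {
                    "mirna_id": mirna_id,
                    "gene_id": gene_id,
                    "region": hit.region,
                    "target_start": hit.target_start,
                    "target_end": hit.target_end,
                    "mfe": hit.mfe,
                    "pairing": hit.pairing,
                    "mirna_direction": direction,
                    "gene_direction": want,
                }
            )
    return pd.DataFrame(
        rows,
        columns=[
            "mirna_id",
            "gene_id",
            "region",
            "target_start",
            "target_end",
            "mfe",
            "pairing",
            "mirna_direction",
            "gene_direction",
        ],
    )
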