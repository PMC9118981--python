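"""Seeded generators for every input the pipeline consumes.

Each generator is a pure function of its arguments (identical seed, bit
identical output) and returns the planted ground truth alongside the
artifact, so downstream stages can be tested end to end without any
external data.  Protein backgrounds are uniform over the 20 residues —
unrealistic for proteomes, but it makes the motif false-positive rate
analytically checkable.  Ion tables are produced by atom-level Monte Carlo
pairing, deliberately independent of the closed-form isotopomer model so
the two act as mutual oracles.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .align import AnchorSpec
from .gcms import Chromatogram
from .isotopes import NATURAL_15N, IonTable, IsotopeConfig
from .kinetics import KineticParams, RateObservation, mm_rate
from .motifs import AMINO_ACIDS, CAH_MOTIF, MotifPattern, ProteinRecord, parse_pattern

_AA = np.array(list(AMINO_ACIDS))


def _random_residues(rng: np.random.Generator, length: int) -> str:
    return "".join(rng.choice(_AA, size=length))


def _instantiate_motif(rng: np.random.Generator, pattern: MotifPattern) -> str:
    out = []
    for allowed, wild in zip(pattern.positions, pattern.wildcard):
        out.append(rng.choice(_AA) if wild else next(iter(allowed)))
    return "".join(out)


@dataclass(frozen=True)
class ProteinTruth:
    records: list[ProteinRecord]
    reference: AnchorSpec
    verdicts: pd.DataFrame  # seq_id, verdict


def gen_proteins(
    n_pos: int,
    n_neg: int,
    n_barbiturase_like: int = 0,
    length_range: tuple[int, int] = (340, 400),
    seed: int = 0,
    *,
    pattern_text: str = CAH_MOTIF,
    mutation_rate: float = 0.02,
) -> ProteinTruth:
    """Synthetic FASTA-ready records with planted classification truth.

    A synthetic reference (R at positions 194 and 324) is generated first.
    Positives are point-mutated copies of the reference with one motif
    instance planted in the final quarter; barbiturase-like records are the
    same but with the first anchor arginine substituted; negatives are
    i.i.d. uniform residue strings.  Point mutations never touch the
    anchors or the motif window, so verdicts are guaranteed by
    construction.
    """
    lo, hi = length_range
    pattern = parse_pattern(pattern_text)
    if lo <= max(324, len(pattern)) or lo > hi:
        raise ValueError("length range must exceed the anchor span (>= 325) and be ordered")
    rng = np.random.default_rng(seed)

    ref_len = hi
    ref = list(_random_residues(rng, ref_len))
    ref[193], ref[323] = "R", "R"
    reference = AnchorSpec(reference_id="synthetic_reference", reference_sequence="".join(ref))

    records: list[ProteinRecord] = []
    rows: list[tuple[str, str]] = []

    def planted(seq_id: str, break_anchor: bool) -> ProteinRecord:
        seq = list(reference.reference_sequence)
        # Plant the motif in the final quarter, clear of the 324 anchor.
        start_min = max(int(np.ceil(0.75 * ref_len)) + 1, 325)
        start = int(rng.integers(start_min, ref_len - len(pattern) + 1))  # 1-based
        motif_seq = _instantiate_motif(rng, pattern)
        seq[start - 1 : start - 1 + len(pattern)] = list(motif_seq)
        protected = set(range(start - 1, start - 1 + len(pattern))) | {193, 323}
        n_mut = rng.binomial(ref_len, mutation_rate)
        for _ in range(n_mut):
            i = int(rng.integers(0, ref_len))
            if i in protected:
                continue
            seq[i] = str(rng.choice(_AA))
        if break_anchor:
            seq[193] = "K"
        return ProteinRecord(id=seq_id, residues="".join(seq))

    for k in range(n_pos):
        rec = planted(f"pos_{k:03d}", break_anchor=False)
        records.append(rec)
        rows.append((rec.id, "CAH-candidate"))
    for k in range(n_barbiturase_like):
        rec = planted(f"barb_{k:03d}", break_anchor=True)
        records.append(rec)
        rows.append((rec.id, "barbiturase-like"))
    for k in range(n_neg):
        length = int(rng.integers(lo, hi + 1))
        rec = ProteinRecord(id=f"neg_{k:03d}", residues=_random_residues(rng, length))
        records.append(rec)
        rows.append((rec.id, "negative"))

    return ProteinTruth(
        records=records,
        reference=reference,
        verdicts=pd.DataFrame(rows, columns=["seq_id", "verdict"]),
    )


@dataclass(frozen=True)
class IonTableTruth:
    ions: IonTable
    f_intra: float
    air_fraction: float
    n_reaction_n2: int
    n_air_n2: int
    airfree_x: float  # 29/30 ratio of the reaction-derived gas alone


def gen_ion_table(
    compound: str,
    f_intra: float,
    n_molecules: int,
    air_fraction: float = 0.0,
    config: IsotopeConfig = IsotopeConfig(),
    seed: int = 0,
) -> IonTableTruth:
    """Atom-level Monte-Carlo N₂ isotopomer sampling plus air contamination.

    Each substrate molecule is fully ¹⁵N-labeled with probability
    ``label_mix_fraction``; individual atoms honor the isotopic purities.
    Molecules react intramolecularly with probability ``f_intra`` (urea:
    both atoms pair; biuret: two atoms pair, the third joins the scrambled
    pool); all other atoms join the pool, which is shuffled and paired.
    Air N₂ (natural ¹⁵N abundance) is added so that it makes up
    ``air_fraction`` of all N₂ in the final table.
    """
    if compound not in ("urea", "biuret"):
        raise ValueError(f"unknown compound {compound!r}")
    if not 0.0 <= f_intra <= 1.0:
        raise ValueError("f_intra must be in [0, 1]")
    if not 0.0 <= air_fraction < 1.0:
        raise ValueError("air_fraction must be in [0, 1)")
    if n_molecules < 1:
        raise ValueError("need at least one molecule")
    rng = np.random.default_rng(seed)
    n_atoms_per_mol = 2 if compound == "urea" else 3

    heavy_mol = rng.random(n_molecules) < config.label_mix_fraction
    intra_mol = rng.random(n_molecules) < f_intra
    # Atom isotopes: heavy molecules are 15N w.p. heavy_purity, light are
    # 15N w.p. (1 - light_purity).
    p15 = np.where(heavy_mol, config.heavy_purity, 1.0 - config.light_purity)
    atoms = rng.random((n_molecules, n_atoms_per_mol)) < p15[:, None]  # True = 15N

    counts = np.zeros(3, dtype=np.int64)  # m/z 28, 29, 30

    # Intramolecular pairs: the first two atoms of each intra molecule.
    intra_atoms = atoms[intra_mol]
    if len(intra_atoms):
        masses = intra_atoms[:, 0].astype(int) + intra_atoms[:, 1].astype(int)
        counts += np.bincount(masses, minlength=3)

    # Scrambled pool: all atoms of inter molecules + third atoms of intra biuret.
    pool_parts = [atoms[~intra_mol].reshape(-1)]
    if n_atoms_per_mol == 3:
        pool_parts.append(atoms[intra_mol][:, 2])
    pool = np.concatenate(pool_parts)
    rng.shuffle(pool)
    n_pairs = len(pool) // 2
    if n_pairs:
        masses = pool[: 2 * n_pairs : 2].astype(int) + pool[1 : 2 * n_pairs : 2].astype(int)
        counts += np.bincount(masses, minlength=3)

    n_rxn = int(counts.sum())
    airfree_x = counts[1] / counts[2] if counts[2] else float("inf")

    n_air = int(round(air_fraction / (1.0 - air_fraction) * n_rxn))
    if n_air:
        air_atoms = rng.random((n_air, 2)) < NATURAL_15N
        masses = air_atoms[:, 0].astype(int) + air_atoms[:, 1].astype(int)
        counts += np.bincount(masses, minlength=3)

    ions = IonTable(area28=float(counts[0]), area29=float(counts[1]), area30=float(counts[2]))
    return IonTableTruth(
        ions=ions,
        f_intra=f_intra,
        air_fraction=air_fraction,
        n_reaction_n2=n_rxn,
        n_air_n2=n_air,
        airfree_x=float(airfree_x),
    )


@dataclass(frozen=True)
class PlateTruth:
    plate: pd.DataFrame  # well, role, concentration, response
    sample_concentrations: dict[str, float]
    slope: float
    intercept: float


def gen_plate(
    slope: float,
    intercept: float,
    standard_concs: tuple[float, ...],
    sample_concs: dict[str, float],
    noise_sd: float = 0.0,
    seed: int = 0,
) -> PlateTruth:
    """Tidy plate table: linear response plus Gaussian read noise."""
    if slope == 0:
        raise ValueError("slope must be non-zero")
    rng = np.random.default_rng(seed)
    rows = []
    for i, conc in enumerate(standard_concs):
        resp = intercept + slope * conc + rng.normal(0.0, noise_sd)
        rows.append((f"std_{i:02d}", "standard", conc, resp))
    for name, conc in sample_concs.items():
        resp = intercept + slope * conc + rng.normal(0.0, noise_sd)
        rows.append((name, "sample", np.nan, resp))
    plate = pd.DataFrame(rows, columns=["well", "role", "concentration", "response"])
    return PlateTruth(
        plate=plate, sample_concentrations=dict(sample_concs), slope=slope, intercept=intercept
    )


def gen_rate_data(
    params: KineticParams,
    e0_uM: float,
    substrate_grid_uM: tuple[float, ...],
    cv: float = 0.0,
    seed: int = 0,
) -> list[RateObservation]:
    """Initial-rate observations with multiplicative Gaussian noise."""
    if cv < 0:
        raise ValueError("cv must be non-negative")
    rng = np.random.default_rng(seed)
    out = []
    for s in substrate_grid_uM:
        v = mm_rate(params, e0_uM, s) * (1.0 + rng.normal(0.0, cv))
        out.append(RateObservation(substrate_uM=s, rate_uM_per_s=max(v, 0.0)))
    return out


def gen_chromatogram(
    peaks: list[tuple[float, float, float]],  # (rt_min, sigma_min, area)
    noise_sd: float = 0.0,
    baseline: float = 0.0,
    t_range: tuple[float, float] = (1.0, 3.5),
    dt: float = 0.002,
    seed: int = 0,
) -> Chromatogram:
    """Sum of Gaussian peaks on a flat baseline with white noise."""
    rng = np.random.default_rng(seed)
    t = np.arange(t_range[0], t_range[1] + dt / 2, dt)
    y = np.full_like(t, float(baseline))
    for rt, sigma, area in peaks:
        if not t_range[0] <= rt <= t_range[1]:
            raise ValueError(f"peak retention time {rt} outside the time axis")
        y += area / (sigma * np.sqrt(2 * np.pi)) * np.exp(-0.5 * ((t - rt) / sigma) ** 2)
    if noise_sd > 0:
        y += rng.normal(0.0, noise_sd, size=len(t))
    return Chromatogram(time_min=t, intensity=np.clip(y, 0.0, None))
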