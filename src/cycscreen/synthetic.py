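"""Seeded synthetic-data generators for every pipeline stage.

Two families of generators live here:

* **Sequences** — protein families with the Cyc2 motif architecture (signal
  peptide, A-X-P-X-F-A-R-[Q/K]-[T/Y] upstream motif, 5-residue spacer,
  CXXCH, 4-residue spacer, PXL, then a long weakly conserved porin tail),
  one ancestor per phylogenetic cluster, members mutated at a low rate in
  the cytochrome region and a high rate in the porin region; plus decoy
  classes targeting each screening guard.
* **Spectra/titrations** — heme absorbance band models (oxidized Soret at
  410 nm; reduced Soret at 427 nm with alpha/beta bands at 560/530 nm) and
  reductive titration traces from a two-couple Nernst equilibrium with a
  linearly delivered reductant, emulating an enzyme-driven dye
  equilibration experiment.

All generators are pure functions of their configuration (including the
seed): the same config reproduces byte-identical output.
"""

from __future__ import annotations

import re
import zlib
from dataclasses import dataclass, field

import numpy as np
from scipy.optimize import brentq

from .redox import TitrationTrace
from .screen import ProteinRecord, STANDARD_AA

__all__ = [
    "FamilyConfig",
    "TitrationConfig",
    "gen_cluster_family",
    "gen_decoys",
    "gen_titration",
    "gen_spectrum",
]

_AA = np.array(list(STANDARD_AA))
_NON_CYS = np.array([a for a in STANDARD_AA if a != "C"])

# cytochrome-region geometry (offsets within the region)
_CYT_REGION_LEN = 90
# spacer residues avoid P and L so no accidental flanking-motif match can
# shift the measured spacers away from their designed values (5 and 4)
_SPACER_AA = np.array([a for a in STANDARD_AA if a not in "CPL"])


@dataclass(frozen=True)
class FamilyConfig:
    """A simulated Cyc2 cluster family.

    The cytochrome region (the first ~90 residues after the signal peptide)
    is strongly conserved; the porin tail mutates at a high per-site rate,
    emulating the observed conservation contrast between the two domains.
    Motif sites are frozen by default so every member passes the screen by
    construction; the [Q/K] and [T/Y] wildcard positions still sample both
    allowed letters.
    """

    cluster_label: str = "1"
    n_members: int = 20
    length: int = 450
    signal_peptide_len: int = 21
    porin_substitution_rate: float = 0.4
    cytochrome_substitution_rate: float = 0.05
    motif_sites_frozen: bool = True
    seed: int = 0
    member_offset: int = 0  # draw disjoint member sets from the same ancestor

    def __post_init__(self) -> None:
        for name in ("porin_substitution_rate", "cytochrome_substitution_rate"):
            if not (0.0 <= getattr(self, name) < 1.0):
                raise ValueError(f"{name} must be in [0, 1)")
        if self.length < 365:
            raise ValueError("family members must be at least 365 residues")


def _label_code(label: str) -> int:
    return zlib.crc32(str(label).encode()) & 0x7FFFFFFF


def _random_seq(rng: np.random.Generator, n: int, alphabet: np.ndarray = _AA) -> str:
    return "".join(rng.choice(alphabet, size=n))


@dataclass
class _Ancestor:
    seq: str
    motif_positions: np.ndarray  # frozen sites (absolute indices)
    cxxch_start: int
    qk_pos: int
    ty_pos: int
    cyt_start: int
    cyt_end: int


def _make_ancestor(cfg: FamilyConfig) -> _Ancestor:
    """Cluster ancestor: deterministic in (seed, cluster_label) only."""
    rng = np.random.default_rng([cfg.seed, _label_code(cfg.cluster_label), 11])
    sp = _random_seq(rng, cfg.signal_peptide_len, _NON_CYS)
    cyt_start = cfg.signal_peptide_len
    region = list(_random_seq(rng, _CYT_REGION_LEN, _NON_CYS))

    # motif skeleton at a fixed offset inside the cytochrome region:
    # AXPXFAR[Q/K][T/Y] .. 5-residue spacer .. CXXCH .. 4-residue spacer .. PXL
    up_off = 20
    upstream = ["A", rng.choice(_NON_CYS), "P", rng.choice(_NON_CYS), "F", "A", "R", "Q", "T"]
    cxxch = ["C", rng.choice(_NON_CYS), rng.choice(_NON_CYS), "C", "H"]
    pxl = ["P", rng.choice(_NON_CYS), "L"]
    frozen: list[int] = []

    def place(chars: list[str], pos: int) -> int:
        for k, ch in enumerate(chars):
            region[pos + k] = str(ch)
            frozen.append(cyt_start + pos + k)
        return pos + len(chars)

    pos = place(upstream, up_off)
    qk_pos = cyt_start + up_off + 7
    ty_pos = cyt_start + up_off + 8
    pos = place(list(rng.choice(_SPACER_AA, size=5)), pos)  # upstream spacer
    cxxch_start = cyt_start + pos
    pos = place(cxxch, pos)
    pos = place(list(rng.choice(_SPACER_AA, size=4)), pos)  # downstream spacer
    place(pxl, pos)

    cyt_end = cyt_start + _CYT_REGION_LEN
    porin = _random_seq(rng, cfg.length - cyt_end, _NON_CYS)
    seq = sp + "".join(region) + porin
    return _Ancestor(
        seq=_scrub_extra_cxxch(seq, rng, keep_start=cxxch_start),
        motif_positions=np.array(frozen),
        cxxch_start=cxxch_start,
        qk_pos=qk_pos,
        ty_pos=ty_pos,
        cyt_start=cyt_start,
        cyt_end=cyt_end,
    )


_CXXCH_RE = re.compile(r"(?=(C[A-Z]{2}CH))")


def _scrub_extra_cxxch(seq: str, rng: np.random.Generator, keep_start: int | None) -> str:
    """Remove accidental CXXCH windows (outside the intended one, if any)."""
    chars = list(seq)
    while True:
        extra = [
            m.start()
            for m in _CXXCH_RE.finditer("".join(chars))
            if m.start() != keep_start
        ]
        if not extra:
            return "".join(chars)
        for s in extra:
            chars[s] = str(rng.choice(_NON_CYS[_NON_CYS != "H"]))


def _mutate_member(
    anc: _Ancestor, cfg: FamilyConfig, rng: np.random.Generator
) -> str:
    chars = np.array(list(anc.seq))
    n = chars.size
    rates = np.full(n, cfg.porin_substitution_rate)
    rates[anc.cyt_start : anc.cyt_end] = cfg.cytochrome_substitution_rate
    mutate = rng.random(n) < rates
    if cfg.motif_sites_frozen:
        mutate[anc.motif_positions] = False
    for i in np.where(mutate)[0]:
        options = _NON_CYS[_NON_CYS != chars[i]]
        chars[i] = rng.choice(options)
    if cfg.motif_sites_frozen:
        # the bracket positions of the upstream motif sample both letters
        chars[anc.qk_pos] = rng.choice(np.array(["Q", "K"]))
        chars[anc.ty_pos] = rng.choice(np.array(["T", "Y"]))
    return _scrub_extra_cxxch("".join(chars), rng, keep_start=anc.cxxch_start)


def gen_cluster_family(cfg: FamilyConfig) -> tuple[list[ProteinRecord], dict]:
    """Simulate one cluster family; returns (records, truth record)."""
    anc = _make_ancestor(cfg)
    records = []
    for i in range(cfg.n_members):
        rng = np.random.default_rng(
            [cfg.seed, _label_code(cfg.cluster_label), 7, cfg.member_offset + i]
        )
        seq = _mutate_member(anc, cfg, rng)
        records.append(
            ProteinRecord(
                id=f"C{cfg.cluster_label}_m{cfg.member_offset + i:04d}",
                seq=seq,
                description=f"synthetic Cyc2 cluster {cfg.cluster_label} member",
            )
        )
    truth = {
        "cluster_label": cfg.cluster_label,
        "ancestor": anc.seq,
        "cxxch_start": anc.cxxch_start,
        "motif_positions": anc.motif_positions.tolist(),
        "ids": [r.id for r in records],
        "config": cfg,
    }
    return records, truth


def _first_cxxch(seq: str) -> int:
    m = _CXXCH_RE.search(seq)
    return m.start() if m else -1


def gen_decoys(
    kind: str, n: int, seed: int = 0, length: int = 450, cluster_label: str = "decoy"
) -> list[ProteinRecord]:
    """Decoy classes targeting the screening and classification guards.

    ``no_heme_porin``: family-like architecture with every CXXCH ablated;
    ``short_fragment``: a true member truncated below the full-length
    cutoff (motifs intact); ``plain_cytochrome``: CXXCH present but the
    upstream motif ablated.
    """
    base = FamilyConfig(cluster_label=cluster_label, n_members=n, length=length, seed=seed)
    if kind == "no_heme_porin":
        records, _ = gen_cluster_family(base)
        out = []
        for rec in records:
            rng = np.random.default_rng([seed, 101, _label_code(rec.id)])
            out.append(
                ProteinRecord(
                    id=f"decoy_nh_{rec.id}",
                    seq=_scrub_extra_cxxch(rec.seq, rng, keep_start=None),
                    description="synthetic porin decoy without heme motif",
                )
            )
        return out
    if kind == "short_fragment":
        records, _ = gen_cluster_family(base)
        return [
            ProteinRecord(
                id=f"decoy_sf_{rec.id}",
                seq=rec.seq[:300],
                description="synthetic short fragment decoy",
            )
            for rec in records
        ]
    if kind == "plain_cytochrome":
        records, truth = gen_cluster_family(base)
        out = []
        up_re = re.compile(r"PXFAR[QK][TY]".replace("X", "[A-Z]"))
        for rec in records:
            rng = np.random.default_rng([seed, 103, _label_code(rec.id)])
            chars = list(rec.seq)
            cx = _first_cxxch(rec.seq)
            while True:
                m = up_re.search("".join(chars[:cx]))
                if m is None:
                    break
                chars[m.start()] = str(rng.choice(_NON_CYS[_NON_CYS != "P"]))
            out.append(
                ProteinRecord(
                    id=f"decoy_pc_{rec.id}",
                    seq="".join(chars),
                    description="synthetic cytochrome decoy without upstream motif",
                )
            )
        return out
    raise ValueError(f"unknown decoy kind {kind!r}")


# ---------------------------------------------------------------------------
# spectra and titrations

#: Gaussian absorbance bands (center nm, height AU, sigma nm) per state
DEFAULT_BANDS = {
    "oxidized": ((410.0, 1.00, 16.0),),
    "reduced": ((427.0, 1.25, 13.0), (530.0, 0.12, 9.0), (560.0, 0.18, 7.0)),
    "dye_oxidized": ((610.0, 0.80, 30.0),),
}


@dataclass(frozen=True)
class TitrationConfig:
    """Physical model of a reductive dye-equilibration titration.

    Electrons are delivered at a constant rate after a short lag (the
    pre-initiation baseline readings); at each time the solution potential
    is the unique value at which the delivered electrons are shared between
    the heme (one-electron, 25 mV slope) and the dye (two-electron, 12.5 mV
    slope) couples.
    """

    E_m_heme: float = 208.0  # mV
    E_m_dye: float = 217.0  # mV
    n_heme: int = 1
    n_dye: int = 2
    heme_total: float = 5.0  # uM
    dye_total: float = 30.0  # uM
    electron_delivery_rate: float = 0.05  # uM e-/s
    lag_s: float = 120.0  # baseline before the reaction is initiated
    dt: float = 15.0  # s
    duration: float = 3600.0  # s
    noise_sd: float = 0.001  # AU
    seed: int = 0
    full_spectrum: bool = False
    wl_min: float = 350.0
    wl_max: float = 800.0
    bands: dict = field(default_factory=lambda: DEFAULT_BANDS)
    # plateau absorbances for the two-wavelength trace dialect
    a_heme_ox: float = 0.30
    a_heme_red: float = 0.78
    a_dye_ox: float = 0.85
    a_dye_red: float = 0.04

    def __post_init__(self) -> None:
        if self.heme_total <= 0 or self.dye_total <= 0:
            raise ValueError("totals must be positive")
        if self.duration / self.dt < 20:
            raise ValueError("need at least 20 time points")


def _f_red(E: np.ndarray | float, E_m: float, slope: float):
    return 1.0 / (1.0 + np.exp((E - E_m) / slope))


def _solve_potential(e_delivered: float, cfg: TitrationConfig) -> float:
    """Invert total-reduced-equivalents(E) = e_delivered by bisection."""
    capacity = cfg.n_heme * cfg.heme_total + cfg.n_dye * cfg.dye_total
    e = min(max(e_delivered, 1e-9), capacity - 1e-9)

    def g(E: float) -> float:
        return (
            cfg.n_heme * cfg.heme_total * _f_red(E, cfg.E_m_heme, 25.0)
            + cfg.n_dye * cfg.dye_total * _f_red(E, cfg.E_m_dye, 12.5)
            - e
        )

    lo = min(cfg.E_m_heme, cfg.E_m_dye) - 800.0
    hi = max(cfg.E_m_heme, cfg.E_m_dye) + 800.0
    return brentq(g, lo, hi, xtol=1e-10)


def gen_spectrum(state: str, cfg: TitrationConfig | None = None) -> tuple[np.ndarray, np.ndarray]:
    """Band-model absorbance spectrum on a 1-nm grid for one redox state."""
    cfg = cfg or TitrationConfig()
    if state not in cfg.bands:
        raise ValueError(f"unknown state {state!r}; have {sorted(cfg.bands)}")
    wl = np.arange(cfg.wl_min, cfg.wl_max + 1.0, 1.0)
    ab = np.zeros_like(wl)
    for center, height, sigma in cfg.bands[state]:
        ab += height * np.exp(-((wl - center) ** 2) / (2.0 * sigma**2))
    return wl, ab


def gen_titration(cfg: TitrationConfig | None = None) -> tuple[TitrationTrace, dict]:
    """Simulate a reductive titration; returns (trace, truth record).

    The truth record carries the solution potential and both reduced
    fractions at every time point, plus the configuration, so round-trip
    tests can compare the analysis output against the closed form.
    """
    cfg = cfg or TitrationConfig()
    rng = np.random.default_rng(cfg.seed)
    times = np.arange(0.0, cfg.duration + cfg.dt / 2, cfg.dt)
    delivered = np.maximum(times - cfg.lag_s, 0.0) * cfg.electron_delivery_rate
    E = np.array([_solve_potential(e, cfg) for e in delivered])
    f_h = _f_red(E, cfg.E_m_heme, 25.0)
    f_d = _f_red(E, cfg.E_m_dye, 12.5)

    if cfg.full_spectrum:
        wl, spec_ox = gen_spectrum("oxidized", cfg)
        _, spec_red = gen_spectrum("reduced", cfg)
        _, spec_dye = gen_spectrum("dye_oxidized", cfg)
        ab = (
            np.outer(1.0 - f_h, spec_ox)
            + np.outer(f_h, spec_red)
            + np.outer(1.0 - f_d, spec_dye)
        )
        wavelengths = wl
    else:
        a429 = cfg.a_heme_ox + (cfg.a_heme_red - cfg.a_heme_ox) * f_h
        a610 = cfg.a_dye_red + (cfg.a_dye_ox - cfg.a_dye_red) * (1.0 - f_d)
        ab = np.column_stack([a429, a610])
        wavelengths = np.array([429.0, 610.0])
    if cfg.noise_sd > 0:
        ab = ab + rng.normal(0.0, cfg.noise_sd, size=ab.shape)

    trace = TitrationTrace(times=times, wavelengths=wavelengths, absorbance=ab)
    truth = {
        "E": E,
        "f_red_heme": f_h,
        "f_red_dye": f_d,
        "delivered": delivered,
        "config": cfg,
    }
    return trace, truth
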