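"""Synthetic inputs for every pipeline stage, with recorded ground truth.

Four generators emulate the four input kinds the pipeline consumes:

* ``gen_precursors`` — precursor proteins with planted peptides flanked by
  motifs drawn from the cleavage grammar, plus a ground-truth table of
  coordinates and maturation flags;
* ``gen_peaklist`` — neutral monoisotopic masses of a peptide set with
  bounded ppm jitter plus decoy peaks kept >= 10 ppm away from every truth;
* ``gen_dose_response`` — long-format luminescence plates drawn from a
  four-parameter log-logistic mean curve with Gaussian replicate noise;
* ``gen_expression`` — cell-type x gene average-expression tables with
  planted signaling modules and the matching truth partition.

Every generator is a pure function of its spec (including the seed):
identical reruns give identical outputs.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .masses import Modifications, monoisotopic_mass, ppm_error
from .mining import CleavageRuleSet, DEFAULT_RULES

__all__ = [
    "DEFAULT_PEPTIDE_LIBRARY",
    "PrecursorSpec",
    "PlateSpec",
    "ExpressionSpec",
    "gen_precursors",
    "gen_peaklist",
    "gen_dose_response",
    "gen_expression",
]

#: Synthetic peptide library modeled on short amidated cnidarian-style
#: neuropeptides (PRGamide-, RFamide-, LRWamide-like sequences and a few
#: non-amidated or proline-start peptides). The full endogenous library is
#: not reproduced; these cover every motif class of the grammar.
DEFAULT_PEPTIDE_LIBRARY: tuple[str, ...] = (
    "GPRG",      # PRGamide-like tetrapeptide
    "APRG",      # PRGamide-like tetrapeptide
    "QGRF",      # pyroGlu RFamide-like
    "QITRF",     # pyroGlu RFamide-like
    "QGLRW",     # LRWamide-like
    "QGGLRW",    # LRWamide-like
    "GPPQGLRW",  # LRWamide-like, xP start
    "FLRN",      # FLRNamide-like
    "AGVRH",     # VRHamide-like
    "LFHIR",     # HIRamide-like
    "APFH",      # PFHamide-like
    "GLWL",      # non-amidated
    "FNRAA",     # non-amidated, monobasic Rxx-R compatible C-terminus
    "APSSFV",    # non-amidated, xP start
    "ASPFVT",    # non-amidated, xxP start
)

_SIGNAL_ALPHABET = "ALVIFMW"
#: linker residues: no basics, acidics, Q, P or G, so linkers can never
#: complete a motif or an amide donor
_LINKER_ALPHABET = "ASTNVILFHWY"
_DIBASIC = ("KR", "RR", "RK", "KK")
_ACIDIC = ("EE", "DD", "ED", "DE")
_NOFLANK = ("Q-start", "xP-start", "xxP-start")


@dataclass(frozen=True)
class PrecursorSpec:
    n_precursors: int = 20
    peptide_library: tuple[str, ...] = DEFAULT_PEPTIDE_LIBRARY
    copies_per_precursor: tuple[int, int] = (1, 4)
    nterm_motif_choice: tuple[str, ...] | None = None  # None: all legal motifs
    cterm_motif_choice: tuple[str, ...] | None = None
    amidation_fraction: float = 0.6
    linker_length: tuple[int, int] = (4, 8)
    seed: int = 0

    def validate(self) -> None:
        if self.n_precursors < 0:
            raise ValueError("n_precursors must be >= 0")
        if not 0 <= self.amidation_fraction <= 1:
            raise ValueError("amidation_fraction must be in [0, 1]")
        if self.copies_per_precursor[0] < 1 or self.copies_per_precursor[0] > self.copies_per_precursor[1]:
            raise ValueError("invalid copies_per_precursor range")
        if self.linker_length[0] < 1 or self.linker_length[0] > self.linker_length[1]:
            raise ValueError("invalid linker_length range")
        if self.n_precursors and not self.peptide_library:
            raise ValueError("peptide_library must be non-empty")


def _legal_nterm_motifs(peptide: str, choices: tuple[str, ...] | None) -> list[str]:
    """Motifs from the grammar that guarantee the planted peptide is minable.

    Acidic-pair flanks put a D/E two residues before peptide position 2, so
    a Q at position 2 or a P at position 3/4 would license an *internal*
    alternative cut; such peptides are only planted behind dibasic flanks
    or no-flank starts (whose acidic support sits one residue further out).
    """
    q_or_p = peptide.startswith("Q") or "P" in peptide[1:3]
    internal_risk = (len(peptide) > 1 and peptide[1] == "Q") or "P" in peptide[2:4]
    legal = list(_DIBASIC)
    if q_or_p and not internal_risk:
        legal += list(_ACIDIC)
    if peptide.startswith("Q"):
        legal.append("Q-start")
    if len(peptide) > 1 and peptide[1] == "P":
        legal.append("xP-start")
    if len(peptide) > 2 and peptide[2] == "P":
        legal.append("xxP-start")
    if choices is not None:
        legal = [m for m in legal if m in choices] or list(_DIBASIC)
    return legal


def gen_precursors(spec: PrecursorSpec) -> tuple[list[tuple[str, str]], pd.DataFrame]:
    """Generate precursor records and the ground-truth peptide table.

    Returns ``(fasta_records, truth)`` where ``fasta_records`` is a list of
    (id, sequence) pairs and ``truth`` records, per planted peptide, the
    precursor id, 0-based half-open raw coordinates, raw and matured
    sequence, maturation flags and the flanking motifs used. A
    ``signal_end`` column on the truth table gives the annotated signal
    boundary of each precursor.

    Peptides containing an internal dibasic motif are planted anyway but
    flagged (``over_cleavage_risk``) and a warning is issued, since the
    grammar would cut inside them.
    """
    spec.validate()
    rng = np.random.default_rng(spec.seed)
    records: list[tuple[str, str]] = []
    rows: list[dict] = []

    for i in range(spec.n_precursors):
        pid = f"prec{i:04d}"
        signal_len = int(rng.integers(18, 25))
        seq = "M" + "".join(rng.choice(list(_SIGNAL_ALPHABET), size=signal_len))
        signal_end = len(seq)
        n_copies = int(rng.integers(spec.copies_per_precursor[0], spec.copies_per_precursor[1] + 1))
        for c in range(n_copies):
            peptide = str(rng.choice(spec.peptide_library))
            nterm = str(rng.choice(_legal_nterm_motifs(peptide, spec.nterm_motif_choice)))
            # peptides ending in a basic residue would fuse with a dibasic
            # flank, and a genuine trailing G before a basic flank *is* an
            # amide donor, so both classes are always planted amidated
            forced_amide = peptide[-1] in "KRG"
            amidated = bool(rng.random() < spec.amidation_fraction) or forced_amide
            monobasic_ok = (not amidated) and len(peptide) >= 3 and peptide[-3] == "R"
            cterm_options = list(_DIBASIC) + (["R"] if monobasic_ok else [])
            if spec.cterm_motif_choice is not None:
                cterm_options = [m for m in cterm_options if m in spec.cterm_motif_choice] or list(_DIBASIC)
            cterm = str(rng.choice(cterm_options))

            linker = "".join(
                rng.choice(list(_LINKER_ALPHABET), size=int(rng.integers(spec.linker_length[0], spec.linker_length[1] + 1)))
            )
            if nterm in _NOFLANK:
                # no flank residues removed: an acidic residue two positions
                # upstream supports the cut at the peptide start without
                # also supporting a cut one residue further in
                seq += linker + "E" + str(rng.choice(list(_LINKER_ALPHABET)))
            else:
                seq += linker + nterm

            raw = peptide + ("G" if amidated else "")
            start = len(seq)
            seq += raw
            end = len(seq)
            seq += cterm

            over_risk = any(raw[j] in "KR" and raw[j + 1] in "KR" for j in range(len(raw) - 1))
            if over_risk:
                warnings.warn(
                    f"{pid}: planted peptide {peptide!r} contains an internal dibasic "
                    "motif and would be over-cleaved by the grammar",
                    stacklevel=2,
                )
            rows.append(
                dict(
                    precursor_id=pid,
                    start=start,
                    end=end,
                    raw_sequence=raw,
                    sequence=peptide,
                    pyro_glu="Q" if peptide.startswith("Q") else "",
                    amidated=amidated,
                    nterm_motif=nterm,
                    cterm_motif=cterm,
                    signal_end=signal_end,
                    over_cleavage_risk=over_risk,
                )
            )
        # trailing linker so the last flank is not at the sequence end
        seq += "".join(rng.choice(list(_LINKER_ALPHABET), size=int(rng.integers(spec.linker_length[0], spec.linker_length[1] + 1))))
        records.append((pid, seq))

    truth = pd.DataFrame(
        rows,
        columns=[
            "precursor_id", "start", "end", "raw_sequence", "sequence",
            "pyro_glu", "amidated", "nterm_motif", "cterm_motif",
            "signal_end", "over_cleavage_risk",
        ],
    )
    return records, truth


@dataclass(frozen=True)
class PlateSpec:
    """One synthetic dose-response plate (a receptor-peptide series)."""

    true_ec50: float = 1e-8
    true_slope: float = 1.0
    lower: float = 0.0
    upper: float = 1.0
    concentrations: tuple[float, ...] = tuple(np.logspace(-13, -4, 10))
    n_replicates: int = 9
    noise_sd: float = 0.05  # fraction of (upper - lower)
    receptor_id: str = "R1"
    peptide_id: str = "pep1"
    seed: int = 0

    def validate(self) -> None:
        conc = np.asarray(self.concentrations)
        if conc.size == 0 or np.any(conc <= 0):
            raise ValueError("concentrations must be strictly positive")
        if np.any(np.diff(conc) <= 0):
            raise ValueError("concentrations must be sorted ascending")
        if self.n_replicates < 1:
            raise ValueError("n_replicates must be >= 1")
        if self.true_ec50 <= 0:
            raise ValueError("true_ec50 must be positive")
        if self.noise_sd < 0:
            raise ValueError("noise_sd must be >= 0")


def gen_dose_response(spec: PlateSpec) -> pd.DataFrame:
    """Draw a long-format plate from the 4PL mean curve.

    The positive-slope convention is used: responses increase with
    concentration, equal (lower+upper)/2 at the true EC50, and approach the
    lower asymptote as the concentration goes to zero. Noise is Gaussian on
    the response scale with sd ``noise_sd * (upper - lower)``.
    """
    spec.validate()
    rng = np.random.default_rng(spec.seed)
    x = np.asarray(spec.concentrations)
    mean = spec.lower + (spec.upper - spec.lower) / (
        1.0 + (spec.true_ec50 / x) ** spec.true_slope
    )
    rows = []
    for rep in range(spec.n_replicates):
        noise = rng.normal(0.0, spec.noise_sd * (spec.upper - spec.lower), size=x.size)
        for xi, mi, ni in zip(x, mean, noise):
            rows.append(
                dict(
                    receptor=spec.receptor_id,
                    peptide=spec.peptide_id,
                    concentration_M=xi,
                    replicate=rep,
                    response=mi + ni,
                )
            )
    return pd.DataFrame(rows)


def gen_peaklist(
    peptides: pd.DataFrame,
    ppm_jitter: float = 2.0,
    n_decoys: int = 0,
    seed: int = 0,
) -> pd.DataFrame:
    """Peak list with one jittered peak per peptide plus decoys.

    ``peptides`` needs columns ``peptide_id``, ``sequence`` and optionally
    ``pyro_glu``/``amidated``. True peaks are perturbed by at most
    ``ppm_jitter`` ppm (uniform); decoy masses are sampled uniformly over
    the true-mass range (widened 1% on both sides) and rejected until they
    are >= 10 ppm from every true mass, which keeps scoring unambiguous at
    a 5 ppm matching tolerance.
    """
    if ppm_jitter < 0:
        raise ValueError("ppm_jitter must be >= 0")
    rng = np.random.default_rng(seed)
    rows = []
    true_masses = []
    for row in peptides.itertuples(index=False):
        mods = Modifications(
            pyro_glu=str(getattr(row, "pyro_glu", "") or ""),
            amidated=bool(getattr(row, "amidated", False)),
        )
        m = monoisotopic_mass(row.sequence, mods)
        true_masses.append(m)
        jit = rng.uniform(-ppm_jitter, ppm_jitter) if ppm_jitter else 0.0
        rows.append(
            dict(peak_id=f"peak_{row.peptide_id}", mass_da=m * (1 + jit * 1e-6), is_decoy=False)
        )
    tm = np.array(true_masses) if true_masses else np.array([300.0, 2000.0])
    lo, hi = tm.min() * 0.99, tm.max() * 1.01
    k = 0
    while k < n_decoys:
        cand = rng.uniform(lo, hi)
        if tm.size and np.min([abs(ppm_error(cand, t)) for t in tm]) < 10.0:
            continue
        rows.append(dict(peak_id=f"decoy{k:04d}", mass_da=cand, is_decoy=True))
        k += 1
    return pd.DataFrame(rows, columns=["peak_id", "mass_da", "is_decoy"])


@dataclass(frozen=True)
class ExpressionSpec:
    """Cell-type expression table with planted peptidergic modules."""

    n_celltypes: int = 12
    pairs: tuple[tuple[str, str, float], ...] = (
        ("pep1", "R1", 1e-8),
        ("pep2", "R2", 1e-9),
        ("pep3", "R3", 1e-7),
    )
    planted_modules: tuple[tuple[int, ...], ...] | None = None  # None: equal split
    within_module_expression: float = 5.0
    background_expression: float = 0.0
    expression_jitter: float = 0.1  # lognormal sigma on non-zero means
    seed: int = 0

    def resolved_modules(self) -> tuple[tuple[int, ...], ...]:
        if self.planted_modules is not None:
            flat = sorted(i for m in self.planted_modules for i in m)
            if flat != list(range(self.n_celltypes)):
                raise ValueError("planted_modules must partition the cell types exactly once")
            return self.planted_modules
        n_mod = min(len(self.pairs), self.n_celltypes)
        return tuple(
            tuple(range(m * self.n_celltypes // n_mod, (m + 1) * self.n_celltypes // n_mod))
            for m in range(n_mod)
        )

    def validate(self) -> None:
        if self.n_celltypes < 1 or not self.pairs:
            raise ValueError("need >= 1 cell type and >= 1 pair")
        if self.within_module_expression < 0 or self.background_expression < 0:
            raise ValueError("expression means must be >= 0")
        self.resolved_modules()


def gen_expression(spec: ExpressionSpec) -> tuple[pd.DataFrame, pd.Series]:
    """Generate (expression table, truth partition).

    Each planted module is assigned a subset of the (peptide, receptor)
    pairs round-robin; its cell types express those genes at the
    within-module mean, everything else at the background mean, both
    multiplied by a lognormal jitter. The truth partition maps cell type
    to module index.
    """
    spec.validate()
    rng = np.random.default_rng(spec.seed)
    modules = spec.resolved_modules()
    celltypes = [f"ct{i:02d}" for i in range(spec.n_celltypes)]
    genes: list[str] = []
    for pep, rec, _ in spec.pairs:
        for g in (pep, rec):
            if g not in genes:
                genes.append(g)

    pair_module = {idx: idx % len(modules) for idx in range(len(spec.pairs))}
    expr = pd.DataFrame(
        spec.background_expression, index=celltypes, columns=genes, dtype=float
    )
    for idx, (pep, rec, _) in enumerate(spec.pairs):
        for ct_i in modules[pair_module[idx]]:
            expr.loc[celltypes[ct_i], [pep, rec]] = spec.within_module_expression
    jitter = rng.lognormal(0.0, spec.expression_jitter, size=expr.shape)
    expr = expr * jitter

    partition = pd.Series(
        {celltypes[i]: m for m, members in enumerate(modules) for i in members},
        name="module",
    ).loc[celltypes]
    return expr, partition
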