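"""End-to-end pipeline: simulate -> mine -> match -> fit -> network.

Each stage writes its CSV artifacts into the output directory and appends a
block to ``manifest.json`` recording the parameters, the per-stage seed and
the row counts of every output, so identical config+seed runs produce
byte-identical manifests. All randomness derives from the global seed via
fixed per-stage substreams.
"""

from __future__ import annotations

import dataclasses
import json
import logging
import time
import tomllib
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from . import connectome as net
from . import doseresponse as dr
from . import io as pio
from . import mining, synthetic
from .masses import match_peptides, matches_to_table
from .mining import CleavageRuleSet, Precursor

logger = logging.getLogger("peptidergic")

__all__ = ["PipelineConfig", "run_pipeline"]

# substream indices: all stage seeds are default_rng([seed, index])
_STAGE_STREAMS = {"precursors": 1, "peaks": 2, "plates": 3, "expression": 4, "network": 5}


@dataclass
class PipelineConfig:
    """Validated per-stage parameter blocks plus the global seed."""

    seed: int = 0
    # simulate
    n_precursors: int = 40
    amidation_fraction: float = 0.6
    ppm_jitter: float = 2.0
    n_decoys: int = 25
    plate_noise_sd: float = 0.05
    n_replicates: int = 9
    plate_pairs: list = field(
        default_factory=lambda: [
            ["R248", "HRPa", 8.9e-9, 1.75],
            ["R36", "PFHa", 1.2e-8, 1.0],
            ["R186", "VRHa", 2.7e-10, 1.0],
        ]
    )
    n_celltypes: int = 12
    within_module_expression: float = 5.0
    background_expression: float = 0.05
    # mine
    min_sites: int = 2
    min_len: int = 3
    max_len: int = 50
    # match
    tol_ppm: float = 5.0
    frag_tol_da: float = 0.02
    # fit
    normalize: str = "none"
    # network
    expr_floor: float = 0.0
    resolution: float = 1.0

    @classmethod
    def from_toml(cls, path) -> "PipelineConfig":
        with open(path, "rb") as fh:
            raw = tomllib.load(fh)
        known = {f.name for f in dataclasses.fields(cls)}
        unknown = set(raw) - known
        if unknown:
            raise ValueError(f"unknown config keys: {sorted(unknown)}")
        return cls(**raw)


def _stage_seed(cfg: PipelineConfig, stage: str) -> list[int]:
    return [cfg.seed, _STAGE_STREAMS[stage]]


def run_pipeline(config: PipelineConfig, outdir) -> Path:
    """Run every stage on synthetic inputs; returns the artifact directory."""
    out = Path(outdir)
    out.mkdir(parents=True, exist_ok=True)
    manifest: dict = {"config": dataclasses.asdict(config), "stages": {}}

    def record(stage: str, params: dict, outputs: dict[str, int]) -> None:
        manifest["stages"][stage] = {"params": params, "outputs": outputs}

    t0 = time.perf_counter()

    # ---- simulate -------------------------------------------------------
    try:
        pspec = synthetic.PrecursorSpec(
            n_precursors=config.n_precursors,
            amidation_fraction=config.amidation_fraction,
            seed=int(np.random.default_rng(_stage_seed(config, "precursors")).integers(2**31)),
        )
        records, truth = synthetic.gen_precursors(pspec)
        pio.write_fasta(records, out / "precursors.fasta")
        sig = truth[["precursor_id", "signal_end"]].drop_duplicates()
        sig.to_csv(out / "signal_annotations.tsv", sep="\t", header=False, index=False)
        n_truth = pio.write_csv(truth, out / "truth_peptides.csv")

        pepin = truth.rename(columns={"precursor_id": "peptide_id"}).copy()
        pepin["peptide_id"] = [
            f"{r.precursor_id}:{r.start}-{r.end}" for r in truth.itertuples(index=False)
        ]
        peaks = synthetic.gen_peaklist(
            pepin,
            ppm_jitter=config.ppm_jitter,
            n_decoys=config.n_decoys,
            seed=int(np.random.default_rng(_stage_seed(config, "peaks")).integers(2**31)),
        )
        n_peaks = pio.write_csv(peaks, out / "peaks.csv")

        plate_frames = []
        plate_rng = np.random.default_rng(_stage_seed(config, "plates"))
        for rec_id, pep_id, ec50, slope in config.plate_pairs:
            ps = synthetic.PlateSpec(
                true_ec50=float(ec50),
                true_slope=float(slope),
                noise_sd=config.plate_noise_sd,
                n_replicates=config.n_replicates,
                receptor_id=str(rec_id),
                peptide_id=str(pep_id),
                seed=int(plate_rng.integers(2**31)),
            )
            plate_frames.append(synthetic.gen_dose_response(ps))
        plates = pd.concat(plate_frames, ignore_index=True)
        n_plates = pio.write_csv(plates, out / "plates.csv")

        espec = synthetic.ExpressionSpec(
            n_celltypes=config.n_celltypes,
            pairs=tuple((p, r, float(e)) for r, p, e, _ in config.plate_pairs),
            within_module_expression=config.within_module_expression,
            background_expression=config.background_expression,
            seed=int(np.random.default_rng(_stage_seed(config, "expression")).integers(2**31)),
        )
        expr, partition = synthetic.gen_expression(espec)
        expr.to_csv(out / "expression.csv")
        partition.rename_axis("cell_type").reset_index().to_csv(
            out / "truth_partition.csv", index=False
        )
        pairs_df = pd.DataFrame(
            [(p, r, float(e)) for r, p, e, _ in config.plate_pairs],
            columns=["peptide", "receptor", "ec50"],
        )
        n_pairs = pio.write_csv(pairs_df, out / "pairs.csv")
        record(
            "simulate",
            dict(n_precursors=config.n_precursors, n_decoys=config.n_decoys,
                 ppm_jitter=config.ppm_jitter, noise_sd=config.plate_noise_sd),
            {"truth_peptides.csv": n_truth, "peaks.csv": n_peaks,
             "plates.csv": n_plates, "pairs.csv": n_pairs,
             "expression.csv": len(expr)},
        )
    except Exception as exc:  # pragma: no cover - stage-named failure path
        raise RuntimeError(f"stage 'simulate' failed: {exc}") from exc

    # ---- mine -----------------------------------------------------------
    try:
        fasta = pio.read_fasta(out / "precursors.fasta")
        sig_map = pio.read_signal_annotations(out / "signal_annotations.tsv")
        rules = CleavageRuleSet()
        precursors = [
            Precursor(rid, seq, signal_end=sig_map.get(rid, 0)) for rid, seq in fasta
        ]
        retained = mining.filter_repetitive(precursors, min_sites=config.min_sites, rules=rules)
        peptides = []
        for prec in retained:
            peptides.extend(
                mining.extract_peptides(prec, rules, config.min_len, config.max_len)
            )
        mined = mining.peptides_to_table(peptides)
        mined.insert(
            0, "peptide_id",
            [f"{p.precursor_id}:{p.start}-{p.end}" for p in peptides],
        )
        n_mined = pio.write_csv(mined, out / "mined_peptides.csv")
        record("mine", dict(min_sites=config.min_sites, min_len=config.min_len,
                            max_len=config.max_len),
               {"mined_peptides.csv": n_mined})
    except Exception as exc:
        raise RuntimeError(f"stage 'mine' failed: {exc}") from exc

    # ---- match ----------------------------------------------------------
    try:
        peaks_in = pd.read_csv(out / "peaks.csv")
        matches, un_pep, un_peak = match_peptides(
            mined, peaks_in, tol_ppm=config.tol_ppm, frag_tol_da=config.frag_tol_da
        )
        mtab = matches_to_table(matches)
        n_matches = pio.write_csv(mtab, out / "matches.csv")
        record("match", dict(tol_ppm=config.tol_ppm, frag_tol_da=config.frag_tol_da),
               {"matches.csv": n_matches})
    except Exception as exc:
        raise RuntimeError(f"stage 'match' failed: {exc}") from exc

    # ---- fit ------------------------------------------------------------
    try:
        plates_in = pd.read_csv(out / "plates.csv")
        if config.normalize != "none":
            plates_in = dr.normalize_plate(plates_in, config.normalize)
        fits = [
            dr.fit_4pl(g) for _, g in plates_in.groupby(["receptor", "peptide"])
        ]
        summary = dr.summarize_pairs(fits)
        fit_tab = pd.DataFrame(
            [
                dict(receptor=f.receptor_id, peptide=f.peptide_id,
                     lower=f.lower, upper=f.upper, hill_slope=f.hill_slope,
                     ec50=f.ec50, sse=f.residual_sse, converged=f.converged)
                for f in fits
            ]
        )
        n_fits = pio.write_csv(fit_tab, out / "fits.csv")
        n_summary = pio.write_csv(summary["per_receptor"], out / "pair_summary.csv")
        record("fit", dict(normalize=config.normalize),
               {"fits.csv": n_fits, "pair_summary.csv": n_summary})
    except Exception as exc:
        raise RuntimeError(f"stage 'fit' failed: {exc}") from exc

    # ---- network --------------------------------------------------------
    try:
        expr_in = pd.read_csv(out / "expression.csv", index_col=0)
        pairs_in = pd.read_csv(out / "pairs.csv")
        # prefer fitted EC50s where the fit converged
        fitted = fit_tab[fit_tab["converged"]]
        merged = pairs_in.merge(
            fitted[["receptor", "peptide", "ec50"]],
            on=["receptor", "peptide"], how="left", suffixes=("", "_fit"),
        )
        merged["ec50"] = merged["ec50_fit"].fillna(merged["ec50"])
        graph = net.build_network(
            expr_in, merged[["peptide", "receptor", "ec50"]], expr_floor=config.expr_floor
        )
        seed = int(np.random.default_rng(_stage_seed(config, "network")).integers(2**31))
        modules = net.detect_modules(graph, resolution=config.resolution, seed=seed)
        hubs = net.hub_scores(graph)
        net.write_gexf(graph, out / "network.gexf")
        mod_tab = pd.DataFrame(
            sorted(modules.items()), columns=["cell_type", "module"]
        )
        n_mod = pio.write_csv(mod_tab, out / "modules.csv")
        n_hub = pio.write_csv(hubs, out / "hubs.csv")
        record("network", dict(expr_floor=config.expr_floor,
                               resolution=config.resolution, leiden_seed=seed),
               {"modules.csv": n_mod, "hubs.csv": n_hub,
                "network_edges": graph.number_of_edges()})
    except Exception as exc:
        raise RuntimeError(f"stage 'network' failed: {exc}") from exc

    # timing goes to the log only: the manifest must be byte-reproducible
    (out / "manifest.json").write_text(
        json.dumps(manifest, sort_keys=True, indent=2, default=str) + "\n"
    )
    logger.info("pipeline finished in %.2fs -> %s", time.perf_counter() - t0, out)
    return out
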