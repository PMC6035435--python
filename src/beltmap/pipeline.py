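"""End-to-end pipeline: simulate -> QC -> kernels/scan -> IC-Hap -> CNV.

Every stage writes its outputs before the next stage starts, and each stage
reads only the artifacts of earlier stages, so re-running from intermediate
files equals a fresh run. All coordinates are 1-based inclusive internally;
BED outputs are converted to 0-based half-open with a header note.

Phasing/imputation is an external step in this pipeline: alongside the
observed panel (with missingness and planted errors) the simulate stage
writes a complete, phased panel — the simulator's truth phase standing in
for the output of an external phasing tool — which the scan consumes.
"""

from __future__ import annotations

import dataclasses
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import __version__, cnv, ichap, io, kernels, qc, scan, simulate
from .simulate import SimConfig

logger = logging.getLogger(__name__)


class StageError(RuntimeError):
    def __init__(self, stage: str, cause: Exception):
        super().__init__(f"pipeline stage '{stage}' failed: {cause}")
        self.stage = stage
        self.cause = cause


@dataclass(frozen=True)
class RunConfig:
    """All pipeline parameters; round-trips losslessly through YAML."""

    sim: SimConfig = field(default_factory=SimConfig)
    call_rate: float = 0.95
    mendel: float = 0.002
    maf: float = 0.025
    window_size: int = 40
    step: int = 1
    pc_rule: str = "parallel"  # "parallel" (Horn) or "variance" (cumulative)
    pc_var: float = 0.95
    drop_lod: float = 2.0
    extend_snps: int = 20
    ichap_len_min: int = 4
    ichap_len_max: int = 12
    mean_cov: float = 30.0
    read_len: int = 100
    qpcr_noise_sd: float = 0.1
    seed: int = 0

    def to_dict(self) -> dict:
        d = dataclasses.asdict(self)
        d["sim"]["breeds"] = [list(b) for b in self.sim.breeds]
        return d

    @classmethod
    def from_dict(cls, d: dict) -> "RunConfig":
        d = dict(d)
        simd = dict(d.pop("sim", {}))
        if "breeds" in simd:
            simd["breeds"] = tuple(tuple(b) for b in simd["breeds"])
        return cls(sim=SimConfig(**simd), **d)

    def to_yaml(self, path) -> None:
        with open(path, "w") as fh:
            yaml.safe_dump(self.to_dict(), fh, sort_keys=True)

    @classmethod
    def from_yaml(cls, path) -> "RunConfig":
        with open(path) as fh:
            return cls.from_dict(yaml.safe_load(fh))


def _seeds(master: int, n: int) -> list:
    """Independent per-stage seeds below 2**31 derived from the master seed."""
    ss = np.random.SeedSequence(master)
    return [int(s) % (2**31) for s in ss.generate_state(n)]


# ----------------------------------------------------------------------
def run_pipeline(cfg: RunConfig, outdir) -> dict:
    """Run all stages into ``outdir``; return the machine-readable summary."""
    out = Path(outdir)
    out.mkdir(parents=True, exist_ok=True)
    seed_sim, seed_depth, seed_qpcr = _seeds(cfg.seed, 3)
    summary = {
        "version": __version__,
        "seed": cfg.seed,
        "config": cfg.to_dict(),
    }

    # ---- simulate -----------------------------------------------------
    stage = "simulate"
    try:
        simcfg = dataclasses.replace(cfg.sim, seed=seed_sim)
        panel, pheno, truth = simulate.simulate_panel(simcfg)
        io.write_phased_vcf(panel, out / "observed.vcf")
        truth_panel = simulate.PhasedPanel(
            panel.chrom, panel.snp_ids, panel.pos, truth.true_haps, panel.animal_ids
        )
        io.write_phased_vcf(truth_panel, out / "phased.vcf")
        io.write_phenotypes(pheno, out / "phenotypes.tsv")
        truth.table.to_csv(out / "truth.tsv", sep="\t", index=False)
        pd.DataFrame(truth.trios, columns=["offspring", "sire", "dam"]).to_csv(
            out / "trios.tsv", sep="\t", index=False
        )
        belt_bp = truth.belt_bp
        region = (belt_bp + 500, belt_bp + 6500)
        flanks = [(region[0] - 8000, region[0] - 2001), (region[1] + 2001, region[1] + 8000)]
        ds = simulate.simulate_depth(
            truth,
            region,
            flanks,
            mean_cov=cfg.mean_cov,
            read_len=cfg.read_len,
            seed=seed_depth,
            belt_copies=simcfg.belt_copies,
            chrom_length_bp=simcfg.chrom_length_bp,
            chrom=simcfg.chrom,
        )
        depth_dir = out / "depth"
        depth_dir.mkdir(exist_ok=True)
        for aid, track in ds.depth.items():
            io.write_bedgraph(ds.chrom, ds.track_start, track, depth_dir / f"{aid}.bedgraph")
        io.write_split_reads(ds.split_reads, out / "split_reads.tsv")
        with open(out / "ref_seq.txt", "w") as fh:
            fh.write(f">{ds.chrom}:{ds.track_start}\n{ds.ref_seq}\n")
        qpcr_tab = _qpcr_table(truth, simcfg.belt_copies, cfg.qpcr_noise_sd, seed_qpcr)
        io.write_qpcr(qpcr_tab, out / "qpcr.csv")
        with open(out / "regions.json", "w") as fh:
            json.dump({"candidate": list(region), "flanks": [list(f) for f in flanks],
                       "track_start": ds.track_start, "belt_bp": belt_bp}, fh)
        summary["belt_bp_true"] = belt_bp
    except Exception as e:  # noqa: BLE001
        raise StageError(stage, e) from e

    # ---- qc -----------------------------------------------------------
    stage = "qc"
    try:
        observed = io.read_phased_vcf(out / "observed.vcf")
        trios = [tuple(r) for r in pd.read_csv(out / "trios.tsv", sep="\t").to_numpy()]
        thresholds = qc.QcThresholds(cfg.call_rate, cfg.mendel, cfg.maf)
        _, report = qc.filter_snps(observed, trios, thresholds)
        report.to_tsv(out / "qc_report.tsv")
        summary["qc"] = {"n_snps_in": int(len(report.table)), "n_snps_pass": report.n_pass}
    except Exception as e:  # noqa: BLE001
        raise StageError(stage, e) from e

    # ---- scan ---------------------------------------------------------
    stage = "scan"
    try:
        phased = io.read_phased_vcf(out / "phased.vcf")
        rep = pd.read_csv(out / "qc_report.tsv", sep="\t")
        keep = set(rep.loc[rep["passed"], "snp_id"])
        phased = phased.subset_snps(np.array([s in keep for s in phased.snp_ids]))
        # the QC MAF rule works on observed calls; drop SNPs that are
        # monomorphic in the phased analysis panel itself
        freq = kernels.allele_frequencies(phased.genotypes())
        phased = phased.subset_snps((freq > 0) & (freq < 1))
        pheno = io.read_phenotypes(out / "phenotypes.tsv")
        y = pheno.set_index("animal_id").loc[list(phased.animal_ids), "code"].to_numpy()
        if cfg.pc_rule == "parallel":
            pcs = kernels.parallel_analysis_components(
                phased.genotypes(), seed=_seeds(cfg.seed, 4)[3]
            )
        else:
            pcs = kernels.principal_components(kernels.uar(phased.genotypes()), cfg.pc_var)
        profile = scan.lrt_scan(phased, y, pcs.scores, window=cfg.window_size, step=cfg.step)
        ci = scan.lod_drop_ci(profile, cfg.drop_lod, cfg.extend_snps)
        profile.to_tsv(out / "profile.tsv")
        ci.to_bed(out / "ci.bed", phased.chrom)
        summary["scan"] = {
            "n_pcs": pcs.m,
            "lrt_max": profile.lrt_max,
            "lrt_max_bp": profile.peak_midpoint_bp,
            "initial_ci_bp": list(ci.initial_bp),
            "extended_ci_bp": list(ci.extended_bp),
        }
        ext_snps = ci.extended_snps
    except Exception as e:  # noqa: BLE001
        raise StageError(stage, e) from e

    # ---- ichap --------------------------------------------------------
    stage = "ichap"
    try:
        sub = phased.subset_snps(np.arange(ext_snps[0], ext_snps[1] + 1))
        haps = ichap.find_ic_haps(sub, pheno, cfg.ichap_len_min, cfg.ichap_len_max)
        tab = ichap.ichaps_to_frame(haps)
        tab.to_csv(out / "ichap.tsv", sep="\t", index=False)
        summary["ichap"] = tab.to_dict(orient="records")
    except Exception as e:  # noqa: BLE001
        raise StageError(stage, e) from e

    # ---- cnv ----------------------------------------------------------
    stage = "cnv"
    try:
        with open(out / "regions.json") as fh:
            regions = json.load(fh)
        candidate = tuple(regions["candidate"])
        flanks = [tuple(f) for f in regions["flanks"]]
        qpcr_tab = io.read_qpcr(out / "qpcr.csv")
        split_reads = io.read_split_reads(out / "split_reads.tsv")
        calls = {}
        for aid in phased.animal_ids:
            chrom_, start1, track = io.read_bedgraph(out / "depth" / f"{aid}.bedgraph")
            calls[aid] = cnv.depth_ratio(track, start1, candidate, flanks)
        depth_calls = cnv.calls_to_frame(calls)
        qcalls = {
            aid: cnv.qpcr_copy_ratio(qpcr_tab, aid) for aid in phased.animal_ids
        }
        qpcr_calls = cnv.calls_to_frame(qcalls)
        all_calls = pd.concat([depth_calls, qpcr_calls], ignore_index=True)
        all_calls.to_csv(out / "cnv_calls.tsv", sep="\t", index=False)
        summary["cnv"] = {
            "depth": depth_calls.to_dict(orient="records"),
            "qpcr": qpcr_calls.to_dict(orient="records"),
        }
        if len(split_reads) >= 2:
            with open(out / "ref_seq.txt") as fh:
                fh.readline()
                ref_seq = fh.readline().strip()
            bp = cnv.breakpoints_from_clips(split_reads, ref_seq, ref_offset=regions["track_start"])
            with open(out / "breakpoints.bed", "w") as fh:
                fh.write("# 0-based half-open (converted from 1-based inclusive bp)\n")
                fh.write(f"{panel.chrom}\t{bp.left - 1}\t{bp.right}\tjunction\t{bp.support}\n")
            summary["breakpoints"] = {"left": bp.left, "right": bp.right, "support": bp.support}
    except Exception as e:  # noqa: BLE001
        raise StageError(stage, e) from e

    with open(out / "summary.json", "w") as fh:
        json.dump(summary, fh, indent=2, default=_jsonable)
    logger.info("pipeline finished: LRT_max %.2f at %.0f bp", summary["scan"]["lrt_max"],
                summary["scan"]["lrt_max_bp"])
    return summary


def _jsonable(obj):
    if isinstance(obj, (np.integer,)):
        return int(obj)
    if isinstance(obj, (np.floating,)):
        return float(obj)
    if isinstance(obj, np.ndarray):
        return obj.tolist()
    raise TypeError(f"not JSON serializable: {type(obj)}")


def _qpcr_table(truth, belt_copies: int, noise_sd: float, seed: int) -> pd.DataFrame:
    """One qPCR table for the whole cohort: a shared dilution series plus one
    target/reference Cq pair per animal."""
    copies = truth.copies_per_diplotype(belt_copies)
    rng = np.random.default_rng(seed)
    a, b = simulate.DEFAULT_CURVE
    rows = []
    for amp in ("belt2", "lpo"):
        for d in (1.0, 0.1, 0.01, 0.001):
            cq = a + b * np.log10(2.0 * d) + (rng.normal(0, noise_sd) if noise_sd > 0 else 0.0)
            rows.append(("std", amp, cq, d))
    for j, aid in enumerate(truth.table["animal_id"]):
        for amp, q in (("belt2", float(copies[j])), ("lpo", 2.0)):
            cq = a + b * np.log10(q) + (rng.normal(0, noise_sd) if noise_sd > 0 else 0.0)
            rows.append((aid, amp, cq, np.nan))
    return pd.DataFrame(rows, columns=["sample", "amplicon", "Cq", "dilution"])


def plot_profile(profile, ci=None, path=None):
    """Simple LRT-profile figure (requires matplotlib)."""
    import matplotlib

    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    fig, ax = plt.subplots(figsize=(8, 3))
    ax.plot(profile.table["midpoint_bp"] / 1e6, profile.table["lrt"], lw=0.8)
    if ci is not None:
        ax.axvspan(ci.extended_bp[0] / 1e6, ci.extended_bp[1] / 1e6, alpha=0.2, color="red")
    ax.set_xlabel("position (Mb)")
    ax.set_ylabel("LRT")
    fig.tight_layout()
    if path:
        fig.savefig(path, dpi=120)
        plt.close(fig)
    return fig
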