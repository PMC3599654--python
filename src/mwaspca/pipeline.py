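"""Orchestration: one parameter file -> a deterministic plan of CLI jobs.

The three analysis procedures (blocks -> PCA -> association), plus the
optional simulator, are arranged into stages whose jobs are independent
within a stage: block creation and association split per chromosome, the
similarity matrix splits per subject-chunk pair.  A plan can be executed

* sequentially — every job runs in-process, in plan order; or
* as batch files — one command file per stage is written and nothing is
  computed; submitting the files (in order; lines within a file in any
  order, e.g. as cluster array jobs) is the user's scheduler's job.

Both modes run the identical command lines, so result tables are
byte-identical between them.
"""

from __future__ import annotations

import hashlib
import os
import time
from dataclasses import dataclass, field

import pandas as pd

from .params import ParameterFile


@dataclass(frozen=True)
class Command:
    """One executable job: the CLI argv plus declared inputs/outputs."""

    argv: tuple[str, ...]
    inputs: tuple[str, ...] = ()
    outputs: tuple[str, ...] = ()

    def line(self) -> str:
        return "mwaspca " + " ".join(self.argv)


@dataclass(frozen=True)
class Stage:
    name: str
    commands: tuple[Command, ...]


@dataclass
class JobPlan:
    """Ordered stages; every command's inputs exist or are produced upstream."""

    stages: list[Stage]
    mode: str  # "sequential" | "batch-files"
    out_prefix: str

    def validate(self) -> None:
        produced: set[str] = set()
        for stage in self.stages:
            for cmd in stage.commands:
                for inp in cmd.inputs:
                    if inp not in produced and not os.path.exists(inp):
                        raise ValueError(
                            f"stage {stage.name!r}: input {inp!r} neither exists "
                            "nor is produced upstream"
                        )
            for cmd in stage.commands:
                produced.update(cmd.outputs)

    def all_commands(self) -> list[Command]:
        return [c for s in self.stages for c in s.commands]


def _matrix_subjects(path: str) -> list[str]:
    header = pd.read_csv(path, sep="\t", nrows=0)
    return [str(c) for c in header.columns[2:]]


def _matrix_chromosomes(path: str) -> list[str]:
    col = pd.read_csv(path, sep="\t", usecols=["chrom"], dtype=str)["chrom"]
    out: list[str] = []
    for c in col:
        if not out or out[-1] != c:
            out.append(c)
    return out


def plan(params: ParameterFile) -> JobPlan:
    """Build the deterministic job plan for the selected procedures."""
    from .pca import chunk_pairs  # local import keeps module deps one-way
    from .simulate import preset as sim_preset

    procs = params.procedures
    P = params["out_prefix"]
    stages: list[Stage] = []

    simulate_selected = "simulate" in procs
    matrix = params["matrix"]
    if matrix is None and simulate_selected:
        matrix = f"{P}.matrix.tsv"

    # figure out chromosome list and subject count without running anything
    chroms: list[str] | None = None
    n_subjects: int | None = None
    if matrix is not None and os.path.exists(matrix):
        chroms = _matrix_chromosomes(matrix)
        n_subjects = len(_matrix_subjects(matrix))
    elif simulate_selected:
        cfg = sim_preset(
            params["sim_preset"],
            seed=params["seed"],
            sites_per_chrom_mean=params["sim_sites_per_chrom_mean"],
        )
        chroms = [str(i + 1) for i in range(cfg.n_chromosomes)]
        n_subjects = cfg.n_subjects

    if simulate_selected:
        argv = [
            "simulate",
            "--preset", params["sim_preset"],
            "--seed", str(params["seed"]),
            "--sites-per-chrom-mean", str(params["sim_sites_per_chrom_mean"]),
            "--out", P,
        ]
        stages.append(
            Stage(
                "simulate",
                (Command(tuple(argv), outputs=(f"{P}.matrix.tsv", f"{P}.pheno.tsv")),),
            )
        )

    needs_matrix = [p for p in ("blocks", "pca", "assoc") if p in procs]
    if needs_matrix and matrix is None:
        raise ValueError(
            f"procedure(s) {needs_matrix} need a matrix: give `matrix = ...` "
            "or select the simulate procedure"
        )
    if needs_matrix and chroms is None:
        raise ValueError(f"matrix {matrix!r} does not exist and nothing upstream produces it")
    assert chroms is not None and n_subjects is not None or not needs_matrix

    analysis_matrix = matrix
    block_map_path: str | None = None
    if "blocks" in procs:
        per_chrom = []
        block_args = [
            "--t1", str(params["t1"]), "--t2", str(params["t2"]), "--nt", str(params["nt"]),
        ]
        if params["two_stage"]:
            block_args += [
                "--stage2-t1", str(params["stage2_t1"]),
                "--stage2-t2", str(params["stage2_t2"]),
                "--stage2-nt", str(params["stage2_nt"]),
            ]
        else:
            block_args += ["--single-stage"]
        for c in chroms:
            argv = ["blocks", "--in", matrix, "--chrom", c, "--out", P, *block_args]
            per_chrom.append(
                Command(
                    tuple(argv),
                    inputs=(matrix,),
                    outputs=(
                        f"{P}.chr{c}.level1.bed",
                        f"{P}.chr{c}.level2.bed",
                        f"{P}.chr{c}.blocks.tsv",
                    ),
                )
            )
        stages.append(Stage("blocks", tuple(per_chrom)))
        merge = Command(
            ("merge-blocks", "--out", P, "--chroms", ",".join(chroms)),
            inputs=tuple(o for cmd in per_chrom for o in cmd.outputs),
            outputs=(f"{P}.level1.bed", f"{P}.level2.bed", f"{P}.blocks.tsv"),
        )
        stages.append(Stage("blocks-merge", (merge,)))
        analysis_matrix = f"{P}.blocks.tsv"
        block_map_path = f"{P}.level2.bed"

    pcs_path = params["pcs"]
    if "pca" in procs:
        scratch = f"{P}.pca_scratch"
        common = ["--in", analysis_matrix, "--mode", params["pca_mode"],
                  "--chunk-size", str(params["chunk_size"])]
        if params["regress_out"]:
            common += ["--regress-out", ",".join(params["regress_out"]),
                       "--covariates", params["covariates"]]
        chunk_cmds = []
        for i, j in chunk_pairs(n_subjects, params["chunk_size"]):
            argv = ["pca-chunk", *common, "--row-chunk", str(i), "--col-chunk", str(j),
                    "--scratch", scratch]
            chunk_cmds.append(Command(tuple(argv), inputs=(analysis_matrix,), outputs=()))
        stages.append(Stage("pca-chunks", tuple(chunk_cmds)))
        argv = ["pca-assemble", *common, "--scratch", scratch,
                "--n-pcs", str(params["n_pcs"]), "--n-loadings", str(params["n_loadings"]),
                "--out", P]
        stages.append(
            Stage(
                "pca-assemble",
                (Command(tuple(argv), inputs=(analysis_matrix,),
                         outputs=(f"{P}.eigenvalues.tsv", f"{P}.pcs.tsv")),),
            )
        )
        pcs_path = f"{P}.pcs.tsv"

    if "assoc" in procs:
        pheno = params["phenotype"] or f"{P}.pheno.tsv"
        common = ["--in", analysis_matrix, "--pheno", pheno]
        if params["pheno_column"]:
            common += ["--pheno-column", params["pheno_column"]]
        if block_map_path:
            common += ["--blocks", block_map_path]
        if params["assoc_covariates"]:
            common += ["--use-covs", ",".join(params["assoc_covariates"]),
                       "--covariates", params["covariates"]]
        if params["assoc_n_pcs"] > 0:
            if pcs_path is None:
                raise ValueError(
                    "assoc requests PCs but no `pcs` path is given and the pca "
                    "procedure is not selected"
                )
            common += ["--pcs", pcs_path, "--n-pcs", str(params["assoc_n_pcs"])]
        per_chrom = []
        inputs = (analysis_matrix,) + ((pheno,) if pheno else ())
        for c in chroms:
            argv = ["assoc", *common, "--chrom", c, "--out", P]
            per_chrom.append(
                Command(tuple(argv), inputs=inputs, outputs=(f"{P}.chr{c}.assoc.tsv",))
            )
        stages.append(Stage("assoc", tuple(per_chrom)))
        merge = Command(
            ("merge-assoc", "--out", P, "--chroms", ",".join(chroms)),
            inputs=tuple(o for cmd in per_chrom for o in cmd.outputs),
            outputs=(f"{P}.assoc.tsv", f"{P}.lambda.txt"),
        )
        stages.append(Stage("assoc-merge", (merge,)))

    if not stages:
        raise ValueError("no procedure selected")
    jp = JobPlan(stages=stages, mode=params["execution_mode"], out_prefix=P)
    jp.validate()
    return jp


def _digest(path: str) -> str:
    h = hashlib.sha256()
    with open(path, "rb") as fh:
        for block in iter(lambda: fh.read(1 << 20), b""):
            h.update(block)
    return h.hexdigest()[:12]


@dataclass
class RunReport:
    mode: str
    executed: list[str] = field(default_factory=list)
    batch_files: list[str] = field(default_factory=list)
    log_path: str | None = None


def execute(jp: JobPlan, mode: str | None = None) -> RunReport:
    """Run the plan sequentially, or emit batch command files and stop.

    Sequential mode runs every command in-process in plan order; a failing
    stage aborts everything downstream and the partial run is flagged in the
    log.  Batch mode writes one command file per stage (`.batch.NN_stage.txt`)
    and performs no computation.
    """
    mode = mode or jp.mode
    report = RunReport(mode=mode)
    if mode == "batch-files":
        for idx, stage in enumerate(jp.stages, 1):
            path = f"{jp.out_prefix}.batch.{idx:02d}_{stage.name}.txt"
            with open(path, "w") as fh:
                for cmd in stage.commands:
                    fh.write(cmd.line() + "\n")
            report.batch_files.append(path)
        return report
    if mode != "sequential":
        raise ValueError(f"unknown execution mode {mode!r}")

    from click.testing import CliRunner  # runs the very same command lines in-process

    from .cli import main as cli_main

    log_path = f"{jp.out_prefix}.runlog.txt"
    report.log_path = log_path
    runner = CliRunner()
    with open(log_path, "a") as log:
        for stage in jp.stages:
            for cmd in stage.commands:
                t0 = time.perf_counter()
                result = runner.invoke(cli_main, list(cmd.argv), catch_exceptions=False)
                elapsed = time.perf_counter() - t0
                if result.exit_code != 0:
                    log.write(
                        f"FAIL\t{stage.name}\t{elapsed:.2f}s\t{cmd.line()}\n"
                        f"# downstream stages aborted; partial outputs above this line\n"
                    )
                    raise RuntimeError(
                        f"stage {stage.name!r} failed: {cmd.line()}\n{result.output}"
                    )
                digests = ";".join(
                    f"{os.path.basename(o)}={_digest(o)}"
                    for o in cmd.outputs
                    if os.path.exists(o)
                )
                log.write(f"OK\t{stage.name}\t{elapsed:.2f}s\t{cmd.line()}\t{digests}\n")
                report.executed.append(cmd.line())
    return report
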