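"""Routing and execution: the coordination and verification layer.

A run is described by a start point (the format the user has) and an
end point (the format a downstream program needs).  Valid diploid
routes stop at the PHASE boundary — phasing itself is an external,
manual run — so ``polyphred -> fasta`` is a :class:`NoRoute` for
diploid data, while haploid data (no phasing needed) routes straight
through to FASTA.

Every input file is format-verified (structural signature, never the
file extension) before any transformation touches it, and every step
logs its counts (sites, individuals, conflicts, dropped records) so
each silent drop or resolution of the old manual workflow becomes
auditable.  Runs are deterministic: identical inputs and configuration
produce byte-identical outputs.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

from . import consolidate, matrix as matrix_mod, phase, polyphred, reconstruct
from .errors import FormatMismatch, NoRoute
from .matrix import DEFAULT_ID_RULE, SampleIdRule

START_POINTS = ("polyphred", "sdat", "phase_out")
END_POINTS = ("sdat", "phase_in", "fasta")

# (start, end, ploidy) -> ordered step labels; ploidy None = both
_ROUTES: dict[tuple[str, str, int], list[str]] = {
    ("polyphred", "sdat", 2): [
        "parse_reports", "map_to_reference", "merge_reports",
        "verify_reference", "build_matrix", "write_sdat",
    ],
    ("polyphred", "sdat", 1): [
        "parse_reports", "map_to_reference", "merge_reports",
        "verify_reference", "build_matrix", "write_sdat",
    ],
    ("polyphred", "phase_in", 2): [
        "parse_reports", "map_to_reference", "merge_reports",
        "verify_reference", "build_matrix", "write_phase_input",
    ],
    ("sdat", "phase_in", 2): ["read_sdat", "write_phase_input"],
    ("phase_out", "fasta", 2): [
        "read_sdat", "verify_reference", "parse_phase_output",
        "reconstruct_sequences", "write_fasta",
    ],
    ("polyphred", "fasta", 1): [
        "parse_reports", "map_to_reference", "merge_reports",
        "verify_reference", "build_matrix", "reconstruct_haploid", "write_fasta",
    ],
    ("sdat", "fasta", 1): [
        "read_sdat", "verify_reference", "reconstruct_haploid", "write_fasta",
    ],
}

# input roles per start point; '+' marks a multi-file role
_INPUT_ROLES: dict[str, list[str]] = {
    "polyphred": ["polyphred_report+", "reference"],
    "sdat": ["sdat"],
    "phase_out": ["phase_output", "sdat", "reference"],
}

# roles that additionally need the reference for validation/splicing
_NEEDS_REFERENCE = {"verify_reference", "reconstruct_sequences", "reconstruct_haploid"}

_ROLE_FORMAT = {
    "polyphred_report": "polyphred_report",
    "reference": "fasta",
    "sdat": "sdat",
    "phase_output": "phase_output",
}


@dataclass(frozen=True)
class PipelinePlan:
    """An executable path through the transformation graph."""

    start_point: str
    end_point: str
    ploidy: int
    steps: tuple[str, ...]
    required_inputs: tuple[str, ...]


def plan_route(start: str, end: str, ploidy: int = 2) -> PipelinePlan:
    """Resolve the unique route between two pipeline points.

    Raises :class:`NoRoute` when no automated path exists — notably the
    diploid ``polyphred -> fasta`` request, which requires an external
    PHASE run between the phase-input and phase-output boundaries.
    """
    if start not in START_POINTS:
        raise NoRoute(f"unknown start point {start!r}; valid: {START_POINTS}")
    if end not in END_POINTS:
        raise NoRoute(f"unknown end point {end!r}; valid: {END_POINTS}")
    if ploidy not in (1, 2):
        raise NoRoute(f"ploidy must be 1 or 2: {ploidy}")
    steps = _ROUTES.get((start, end, ploidy))
    if steps is None:
        extra = ""
        if (start, end) in {("polyphred", "fasta"), ("sdat", "fasta")} and ploidy == 2:
            extra = (
                " — diploid haplotypes must be inferred externally: write PHASE input "
                "(end point phase_in), run PHASE manually, then restart from phase_out"
            )
        raise NoRoute(f"no automated {start} -> {end} route for ploidy {ploidy}{extra}")
    roles = list(_INPUT_ROLES[start])
    if "reference" not in [r.rstrip("+") for r in roles] and any(
        s in _NEEDS_REFERENCE for s in steps
    ):
        roles.append("reference")
    return PipelinePlan(start, end, ploidy, tuple(steps), tuple(roles))


@dataclass
class RunConfig:
    """User-tunable knobs, file-configurable and flag-overridable."""

    ploidy: int = 2
    policy: str = "missing"
    id_rule: SampleIdRule = DEFAULT_ID_RULE
    min_score: int = 0
    regions_bed: str | None = None


@dataclass
class RunResult:
    outputs: dict[str, Path] = field(default_factory=dict)
    log_lines: list[str] = field(default_factory=list)

    def log(self, step: str, message: str) -> None:
        self.log_lines.append(f"[{step}] {message}")


def _verify_inputs(plan: PipelinePlan, inputs: dict[str, list[Path]], result: RunResult) -> None:
    """Verification-before-processing: reject any mis-formatted input."""
    for role in plan.required_inputs:
        role_name = role.rstrip("+")
        paths = inputs.get(role_name, [])
        if not paths:
            raise FormatMismatch(f"required input role {role_name!r} not supplied")
        if not role.endswith("+") and len(paths) > 1:
            raise FormatMismatch(f"role {role_name!r} takes exactly one file, got {len(paths)}")
        expected = _ROLE_FORMAT[role_name]
        for path in paths:
            found, diag = polyphred.detect_format(Path(path).read_text())
            if found != expected:
                raise FormatMismatch(
                    f"{path}: expected {expected}, detected {found} ({diag})"
                )
            result.log("verify_format", f"{path}: {found} ({diag})")


def run_pipeline(
    plan: PipelinePlan,
    inputs: dict[str, list],
    out_dir,
    config: RunConfig | None = None,
) -> RunResult:
    """Execute a plan: verify formats, run each step, write outputs + log."""
    config = config or RunConfig()
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    inputs = {role: [Path(p) for p in paths] for role, paths in inputs.items()}
    result = RunResult()

    _verify_inputs(plan, inputs, result)

    reference = None
    if "reference" in inputs:
        reference = consolidate.read_reference_fasta(str(inputs["reference"][0]))
        result.log("load_reference", f"{reference.id}: {len(reference)} bp")

    mask = None
    if config.regions_bed:
        mask = reconstruct.read_bed_mask(Path(config.regions_bed).read_text())
        result.log("load_regions", f"{len(mask)} masked span(s)")

    call_set = None
    gmatrix = None
    haps = None
    records = None

    for step in plan.steps:
        if step == "parse_reports":
            reports = []
            for path in inputs["polyphred_report"]:
                report, summary = polyphred.parse_polyphred_report(
                    path.read_text(), min_score=config.min_score
                )
                reports.append(report)
                result.log(
                    step,
                    f"{path.name}: contig {report.contig_name}, {summary.n_sites} sites, "
                    f"{summary.n_genotypes} genotype records, "
                    f"{summary.n_dropped_low_score} dropped (min_score={config.min_score}), "
                    f"{summary.n_ignored_lines} ignored lines",
                )
        elif step == "map_to_reference":
            pass  # folded into merge_reports; contigs are mapped as they merge
        elif step == "merge_reports":
            call_set = consolidate.merge_reports(reports, reference)
            result.log(
                step,
                f"{len(reports)} contig(s) -> {len(call_set.sites)} sites, "
                f"{len(call_set.read_genotypes)} read genotypes",
            )
        elif step == "read_sdat":
            gmatrix = matrix_mod.read_sdat(inputs["sdat"][0].read_text())
            result.log(
                step,
                f"{len(gmatrix.individuals)} individuals x {len(gmatrix.positions)} sites, "
                f"ploidy {gmatrix.ploidy}",
            )
        elif step == "verify_reference":
            if call_set is not None:
                consolidate.verify_reference_consistency(call_set, reference)
                result.log(step, f"{len(call_set.sites)} site(s) consistent with {reference.id}")
            else:
                consolidate.infer_site_alleles(gmatrix, reference)
                result.log(
                    step,
                    f"{len(gmatrix.positions)} site(s) consistent with {reference.id} "
                    "(alleles inferred from SDAT columns)",
                )
        elif step == "build_matrix":
            gmatrix, inconsistencies = matrix_mod.build_genotype_matrix(
                call_set, ploidy=config.ploidy, rule=config.id_rule, policy=config.policy
            )
            result.log(
                step,
                f"{len(gmatrix.individuals)} individuals, "
                f"{len(inconsistencies.entries)} inconsistency(ies), policy={config.policy}",
            )
            inc_path = out / "inconsistencies.tsv"
            inc_path.write_text(inconsistencies.to_text())
            result.outputs["inconsistencies"] = inc_path
        elif step == "write_sdat":
            path = out / "matrix.sdat"
            path.write_text(matrix_mod.write_sdat(gmatrix))
            result.outputs["sdat"] = path
            result.log(step, path.name)
        elif step == "write_phase_input":
            path = out / "phase_input.txt"
            path.write_text(phase.write_phase_input(gmatrix))
            result.outputs["phase_input"] = path
            result.log(step, path.name)
        elif step == "parse_phase_output":
            haps = phase.parse_phase_output(inputs["phase_output"][0].read_text(), gmatrix)
            flagged = len(haps.phase_flags)
            result.log(
                step,
                f"{len(haps.individuals)} individuals, {len(haps.positions)} loci, "
                f"{flagged} flagged allele position(s)",
            )
        elif step == "reconstruct_sequences":
            sites = dict(zip(gmatrix.positions, gmatrix.site_alleles))
            records = reconstruct.reconstruct_sequences(haps, reference, sites, mask)
            result.log(step, f"{len(records)} full-length sequence(s)")
        elif step == "reconstruct_haploid":
            records = reconstruct.reconstruct_haploid(gmatrix, reference, mask=mask)
            result.log(step, f"{len(records)} full-length sequence(s)")
        elif step == "write_fasta":
            path = out / "haplotypes.fasta"
            path.write_text(reconstruct.write_fasta(records))
            result.outputs["fasta"] = path
            result.log(step, path.name)
        else:  # pragma: no cover - route table and executor must stay in sync
            raise AssertionError(f"unknown step {step!r}")

    log_path = out / "run.log"
    log_path.write_text("\n".join(result.log_lines) + "\n")
    result.outputs["log"] = log_path
    return result
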