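"""Declarative full-pipeline runner: harmonize -> scan -> proximity ->
summarize (-> conserve when an alignment is supplied).

The configuration is a single YAML/JSON mapping of stage inputs, so a
full run is a reproducible artifact; re-running on identical inputs
yields byte-identical TSV/JSON outputs.
"""

from __future__ import annotations

import hashlib
import json
import logging
from dataclasses import dataclass
from pathlib import Path
from typing import Any, Mapping, Sequence

import yaml

from . import __version__
from .architecture import class_summary, load_registry
from .conservation import build_projection, column_cooccurrence, read_region_table
from .core_io import (
    PhosmapError,
    SiteTable,
    read_fasta,
    read_feature_table,
    read_site_table,
    write_site_table,
)
from .harmonization import family_summary, merge_sources, validate_sites
from .motif_scan import cross_reference_hits, parse_literal, parse_pattern, scan
from .proximity import DEFAULT_WINDOW, annotate_proximity
from .report import render_map

logger = logging.getLogger("phosmap")


class ConfigError(PhosmapError):
    pass


def _require(config: Mapping[str, Any], key: str) -> Any:
    if key not in config:
        raise ConfigError(f"missing config key {key!r}")
    return config[key]


def _digest(path: str | Path) -> str:
    h = hashlib.sha256()
    with open(path, "rb") as fh:
        for chunk in iter(lambda: fh.read(65536), b""):
            h.update(chunk)
    return h.hexdigest()[:16]


def load_config(source: str | Path | Mapping[str, Any]) -> dict[str, Any]:
    if isinstance(source, Mapping):
        return dict(source)
    with open(source) as fh:
        config = yaml.safe_load(fh)
    if not isinstance(config, dict):
        raise ConfigError(f"{source}: config must be a mapping")
    return config


def run_pipeline(
    config: str | Path | Mapping[str, Any],
    out_dir: str | Path | None = None,
) -> dict[str, Any]:
    """Execute the full pipeline described by a config mapping.

    Required keys: ``sites`` (list of TSV paths), ``fasta``, ``out_dir``
    (unless passed explicitly).  Optional: ``features``, ``registry``
    (``null``/absent -> packaged registry), ``patterns``, ``literals``,
    ``window``, ``alignment``, ``regions``, ``dialect``, ``strict``,
    ``keep_predicted``, ``min_conserved``.

    Writes merged.tsv, report.json, hits.tsv, prox.tsv, summary.json,
    per-protein maps under maps/, and conservation.tsv when an alignment
    is given.  Returns a summary dict of what was produced.
    """
    config = load_config(config)
    out = Path(out_dir) if out_dir is not None else Path(_require(config, "out_dir"))
    out.mkdir(parents=True, exist_ok=True)
    (out / "maps").mkdir(exist_ok=True)

    fasta_path = _require(config, "fasta")
    site_paths = _require(config, "sites")
    if isinstance(site_paths, (str, Path)):
        site_paths = [site_paths]
    dialect = config.get("dialect", "unified")
    strict = bool(config.get("strict", False))
    window = int(config.get("window", DEFAULT_WINDOW))

    run_log: dict[str, Any] = {
        "phosmap_version": __version__,
        "inputs": {
            "fasta": {"path": str(fasta_path), "sha256_16": _digest(fasta_path)},
            "sites": [
                {"path": str(p), "sha256_16": _digest(p)} for p in site_paths
            ],
        },
        "window": window,
    }
    if "seed" in config:
        run_log["seed"] = config["seed"]

    try:
        proteins = read_fasta(fasta_path)
        parse_errors = []
        per_source = []
        for path in site_paths:
            result = read_site_table(path, dialect=dialect, strict=strict)
            parse_errors.extend(
                {"path": str(path), "line": e.line, "message": e.message}
                for e in result.errors
            )
            per_source.append(SiteTable.from_sites(result))

        merged_raw, conflicts = merge_sources(per_source)
        table, validation = validate_sites(
            merged_raw,
            proteins,
            keep_predicted=bool(config.get("keep_predicted", False)),
            strict=strict,
        )
        write_site_table(table, out / "merged.tsv")

        patterns = [parse_pattern(p) for p in config.get("patterns", [])]
        patterns += [parse_literal(l) for l in config.get("literals", [])]
        hits = []
        for protein in proteins:
            for pattern in patterns:
                hits.extend(scan(protein, pattern, table))
        hits = cross_reference_hits(hits, table)
        _write_hits(hits, out / "hits.tsv")

        features = (
            read_feature_table(config["features"]) if config.get("features") else []
        )
        annotations = annotate_proximity(table, features, window=window)
        _write_proximity(annotations, out / "prox.tsv")

        registry = load_registry(config.get("registry"))
        summaries = class_summary(registry, table)
        census = family_summary(proteins, table, registry.family_map)
        summary = {
            "validation": validation.to_dict(),
            "merge_conflicts": [
                {"accession": a, "position": p, "residues": sorted(r)}
                for a, p, r in conflicts
            ],
            "parse_errors": parse_errors,
            "n_proteins": len(proteins),
            "n_sites": len(table),
            "n_motif_hits": len(hits),
            "n_proximity_annotations": len(annotations),
            "n_within_window": sum(1 for a in annotations if a.within_window),
            "class_summary": {k: v.to_dict() for k, v in summaries.items()},
            "family_census": [
                {
                    "family": r.family,
                    "n_chains": r.n_chains,
                    "n_chains_with_sites": r.n_chains_with_sites,
                    "chains_without_sites": list(r.chains_without_sites),
                }
                for r in census
            ],
            "run_log": run_log,
        }
        with open(out / "summary.json", "w") as fh:
            json.dump(summary, fh, indent=1, sort_keys=True)
            fh.write("\n")

        for protein in proteins:
            arch = registry.get(protein.accession)
            document = render_map(protein, arch, table, hits)
            with open(out / "maps" / f"{protein.accession}.json", "w") as fh:
                json.dump(document, fh, indent=1, sort_keys=True)
                fh.write("\n")

        if config.get("alignment"):
            projection = build_projection(config["alignment"])
            regions = (
                read_region_table(config["regions"]) if config.get("regions") else []
            )
            reports = column_cooccurrence(
                projection,
                table,
                hits,
                regions,
                min_sequences=int(config.get("min_conserved", 2)),
            )
            with open(out / "conservation.tsv", "w") as fh:
                fh.write(
                    "column\tsite_accessions\tmotif_accessions\tregions\t"
                    "conserved_phospho\n"
                )
                for r in reports:
                    fh.write(
                        f"{r.column}\t{','.join(r.site_accessions)}\t"
                        f"{','.join(r.motif_accessions)}\t"
                        f"{','.join(r.regions)}\t{r.conserved_phospho}\n"
                    )
        return summary
    except ConfigError:
        raise
    except PhosmapError as exc:
        raise PhosmapError(f"pipeline stage failed: {exc}") from exc


def _write_hits(hits: Sequence, path: Path) -> None:
    ordered = sorted(hits, key=lambda h: (h.accession, h.start, h.pattern_id))
    with open(path, "w") as fh:
        fh.write("accession\tpattern\tstart\tend\tmatched\tprimed\tpriming_site\tstarred\n")
        for h in ordered:
            fh.write(
                f"{h.accession}\t{h.pattern_id}\t{h.start}\t{h.end}\t{h.matched}\t"
                f"{h.primed}\t{h.priming_site if h.priming_site is not None else ''}\t"
                f"{h.starred}\n"
            )


def _write_proximity(annotations: Sequence, path: Path) -> None:
    with open(path, "w") as fh:
        fh.write(
            "accession\tposition\tresidue\tfeature_kind\tfeature_label\t"
            "agent\toffset\trelation\twithin_window\n"
        )
        for a in annotations:
            fh.write(
                f"{a.site.accession}\t{a.site.position}\t{a.site.residue}\t"
                f"{a.feature.kind}\t{a.feature.label}\t{a.feature.agent or ''}\t"
                f"{a.offset}\t{a.relation}\t{a.within_window}\n"
            )
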