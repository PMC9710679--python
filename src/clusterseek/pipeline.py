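"""End-to-end orchestration: hits → filter → context → detect → session."""

from __future__ import annotations

import logging
from typing import Iterable, Sequence, Union

from .context import IpgRow, Placement, build_hierarchy, parse_ipg_table
from .datamodel import DetectParams, FilterParams, Hit, Session, DEFAULT_SYNTENY_WEIGHT
from .detect import assign_ids_and_rank, detect_all
from .genomedb import GeneRecord, all_genes
from .query_io import QueryProfile
from .search_filter import filter_hits

logger = logging.getLogger("clusterseek")


def build_session(
    profile: QueryProfile,
    hits: Sequence[Hit],
    placements: Iterable[Union[IpgRow, GeneRecord, Placement]],
    *,
    filter_params: FilterParams | None = None,
    detect_params: DetectParams | None = None,
    mode: str = "tabular",
    rid: str | None = None,
    synteny_weight: float = DEFAULT_SYNTENY_WEIGHT,
) -> Session:
    """Filter hits, resolve genomic context, detect and rank clusters.

    Returns a complete session ready to be saved, summarized or re-detected.
    Unplaced hit proteins are recorded under ``session.extra["unplaced"]``.
    """
    filter_params = filter_params or FilterParams()
    detect_params = detect_params or DetectParams()
    kept = filter_hits(hits, filter_params)
    logger.info("filtering kept %d of %d hits", len(kept), len(hits))
    organisms, unplaced = build_hierarchy(kept, placements, profile.query_index)
    session = Session(
        queries=list(profile.queries),
        filter=filter_params,
        detect=detect_params,
        organisms=organisms,
        mode=mode,
        rid=rid,
    )
    if unplaced:
        session.extra["unplaced"] = unplaced
    session.clusters = detect_all(session, detect_params, weight_i=synteny_weight)
    assign_ids_and_rank(session)
    logger.info("detected %d clusters in %d organisms",
                len(session.clusters), len(session.organisms))
    return session


def search_tabular(
    profile: QueryProfile,
    hit_table_text: str,
    ipg_table_text: str,
    **kwargs,
) -> Session:
    """Search from a pre-computed 12-column hit table plus IPG placements."""
    from .search_filter import ingest_hit_table

    hits = ingest_hit_table(hit_table_text, profile.query_lengths)
    placements = parse_ipg_table(ipg_table_text)
    return build_session(profile, hits, placements, **kwargs)


def search_local(
    profile: QueryProfile,
    db_prefix: str,
    *,
    executable: str = "blastp",
    **kwargs,
) -> Session:
    """Search against a local database built by makedb.

    Runs the local aligner against ``<prefix>.faa`` (formatted) and resolves
    coordinates from ``<prefix>.sqlite3``; hit subject ids are the store's
    integer indices.
    """
    from pathlib import Path

    from .search_filter import run_local_search

    hits = run_local_search(profile, Path(db_prefix).with_suffix(".faa"),
                            executable=executable)
    placements = all_genes(Path(db_prefix).with_suffix(".sqlite3"))
    kwargs.setdefault("mode", "local")
    return build_session(profile, hits, placements, **kwargs)
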