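"""Retrieval of GEO family archives.

GEO shards series under tranche directories named after the accession with
its last three digits replaced by ``nnn``: the archive for GSE123456 lives
under ``GSE123nnn/GSE123456/miniml/``. Transport is an injected callable so
unit tests (and offline runs) use a stub; the default endpoint is the NCBI
FTP mirror over HTTPS.

Downloads are resumable: a destination file that exists, is non-empty and
starts with a valid gzip header is skipped. Failures are recorded per
accession and never abort the batch; retry uses exponential backoff.
"""

from __future__ import annotations

import gzip
import logging
import re
import time
from dataclasses import dataclass
from pathlib import Path
from typing import Callable, Iterable, Optional, Sequence, Union

from .records import GSE_RE

logger = logging.getLogger(__name__)

DEFAULT_ENDPOINT = "https://ftp.ncbi.nlm.nih.gov/geo/series"

#: transport(url) -> bytes; raises on failure
Transport = Callable[[str], bytes]


@dataclass
class FetchReport:
    accession: str
    attempts: int
    outcome: str  # ok | failed | skipped_cached
    bytes: int = 0
    error_text: str = ""


def tranche_path(accession: str) -> str:
    """Relative repository path of a series' family archive."""
    if not GSE_RE.match(accession):
        raise ValueError(f"not a GSE accession: {accession!r}")
    digits = accession[3:]
    tranche = f"GSE{digits[:-3]}nnn" if len(digits) > 3 else "GSEnnn"
    return f"{tranche}/{accession}/miniml/{accession}_family.xml.tgz"


def _cache_valid(path: Path) -> bool:
    if not path.exists() or path.stat().st_size == 0:
        return False
    try:
        with gzip.open(path, "rb") as fh:
            fh.read(1)
        return True
    except OSError:
        return False


def default_transport(url: str) -> bytes:
    from urllib.request import urlopen

    with urlopen(url, timeout=60) as resp:  # pragma: no cover - network
        return resp.read()


def fetch_archives(
    accessions: Sequence[str],
    dest: Union[str, Path],
    max_retries: int = 3,
    backoff: float = 1.0,
    endpoint: str = DEFAULT_ENDPOINT,
    transport: Optional[Transport] = None,
    sleep: Callable[[float], None] = time.sleep,
) -> list[FetchReport]:
    """Fetch each accession's archive into ``dest``; one report per accession."""
    transport = transport or default_transport
    dest = Path(dest)
    dest.mkdir(parents=True, exist_ok=True)
    reports = []
    for accession in accessions:
        rel = tranche_path(accession)
        target = dest / Path(rel).name
        if _cache_valid(target):
            reports.append(FetchReport(accession, attempts=0, outcome="skipped_cached",
                                       bytes=target.stat().st_size))
            continue
        url = f"{endpoint}/{rel}"
        report = FetchReport(accession, attempts=0, outcome="failed")
        for attempt in range(max_retries + 1):
            report.attempts = attempt + 1
            try:
                data = transport(url)
                target.write_bytes(data)
                report.outcome = "ok"
                report.bytes = len(data)
                break
            except Exception as exc:  # noqa: BLE001 - any transport failure retries
                report.error_text = str(exc)
                if attempt < max_retries:
                    sleep(backoff * 2**attempt)
        reports.append(report)
    rate = success_rate(reports)
    logger.info("fetched %d accessions, success rate %.3f", len(accessions), rate)
    return reports


def success_rate(reports: Iterable[FetchReport]) -> float:
    reports = list(reports)
    if not reports:
        return 1.0
    good = sum(r.outcome in ("ok", "skipped_cached") for r in reports)
    return good / len(reports)


def read_accession_list(path: Union[str, Path]) -> list[str]:
    """One GSE per line; blank lines and ``#`` comments allowed."""
    accessions = []
    for lineno, line in enumerate(
        Path(path).read_text(encoding="utf-8").splitlines(), start=1
    ):
        text = line.split("#", 1)[0].strip()
        if not text:
            continue
        if not GSE_RE.match(text):
            raise ValueError(f"{path}, line {lineno}: not a GSE accession: {text!r}")
        accessions.append(text)
    return accessions
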