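"""Scrubbing of identifying free text from NIfTI-1 headers and JSON sidecars.

The NIfTI-1 format carries no structured subject information, but two
general-purpose text fields — ``descrip`` (80 bytes, at offset 148) and
``intent_name`` (16 bytes, at offset 328) — plus arbitrary header extensions
and the paired JSON sidecar can all hold free text that identifies a person.
``scrub_nifti`` zeroes both text fields, drops every header extension, and
copies the image data bytes verbatim; ``scrub_json`` removes keys matching a
configurable denylist, recursively.

All header surgery happens at the byte level so the guarantee is exact: the
voxel-data byte stream is checksummed before and after and never modified.
"""

from __future__ import annotations

import gzip
import hashlib
import json
import re
import struct
from dataclasses import dataclass, field
from importlib import resources
from pathlib import Path

from .errors import FormatError

_HDR_SIZE = 348
_DESCRIP_OFFSET, _DESCRIP_LEN = 148, 80
_INTENT_NAME_OFFSET, _INTENT_NAME_LEN = 328, 16
_VOX_OFFSET_OFFSET = 108
_MAGIC_OFFSET = 344


@dataclass
class ScrubReport:
    """What was removed from one file; voxel data are never modified."""

    file: str
    fields_cleared: list[tuple[str, int]] = field(default_factory=list)
    extensions_removed: int = 0
    json_keys_removed: list[str] = field(default_factory=list)
    data_checksum_before: str = ""
    data_checksum_after: str = ""

    def as_row(self) -> dict:
        return {
            "file": self.file,
            "fields_cleared": ";".join(f"{n}:{ln}" for n, ln in self.fields_cleared),
            "extensions_removed": self.extensions_removed,
            "json_keys_removed": ";".join(self.json_keys_removed),
            "data_checksum_before": self.data_checksum_before,
            "data_checksum_after": self.data_checksum_after,
        }


def _read_raw(path: Path) -> tuple[bytes, bool]:
    blob = path.read_bytes()
    if blob[:2] == b"\x1f\x8b":
        return gzip.decompress(blob), True
    return blob, False


def scrub_nifti(in_path, out_path) -> ScrubReport:
    """Zero descrip/intent_name, strip header extensions, keep data bytes.

    Accepts plain or gzip-compressed single-file NIfTI-1 (magic ``n+1``).
    Two-file pairs (magic ``ni1``) and NIfTI-2 are refused.  The output is a
    valid NIfTI-1 file with vox_offset 352 and no extensions; idempotent.
    """
    in_path, out_path = Path(in_path), Path(out_path)
    raw, was_gz = _read_raw(in_path)
    if len(raw) < _HDR_SIZE + 4:
        raise FormatError(f"{in_path}: truncated file ({len(raw)} bytes)")
    sizeof_hdr_le = struct.unpack_from("<i", raw, 0)[0]
    if sizeof_hdr_le == 348:
        end = "<"
    elif struct.unpack_from(">i", raw, 0)[0] == 348:
        end = ">"
    elif sizeof_hdr_le == 540 or struct.unpack_from(">i", raw, 0)[0] == 540:
        raise FormatError(f"{in_path}: NIfTI-2 is not supported; use NIfTI-1")
    else:
        raise FormatError(f"{in_path}: not a NIfTI-1 file (bad sizeof_hdr)")
    magic = raw[_MAGIC_OFFSET : _MAGIC_OFFSET + 4]
    if magic[:3] == b"ni1":
        raise FormatError(
            f"{in_path}: two-file (.hdr/.img) NIfTI-1 pairs are not supported"
        )
    if magic[:3] != b"n+1":
        raise FormatError(f"{in_path}: bad NIfTI-1 magic {magic!r}")

    vox_offset = int(struct.unpack_from(end + "f", raw, _VOX_OFFSET_OFFSET)[0])
    if vox_offset < _HDR_SIZE + 4 or vox_offset > len(raw):
        raise FormatError(f"{in_path}: invalid vox_offset {vox_offset}")
    data = raw[vox_offset:]

    # count extensions between the 4-byte extender and the data
    n_ext = 0
    if raw[_HDR_SIZE] != 0:  # extender flag byte
        pos = _HDR_SIZE + 4
        while pos + 8 <= vox_offset:
            esize = struct.unpack_from(end + "i", raw, pos)[0]
            if esize <= 0 or pos + esize > vox_offset:
                raise FormatError(f"{in_path}: malformed header extension")
            n_ext += 1
            pos += esize

    header = bytearray(raw[:_HDR_SIZE])
    header[_DESCRIP_OFFSET : _DESCRIP_OFFSET + _DESCRIP_LEN] = bytes(_DESCRIP_LEN)
    header[_INTENT_NAME_OFFSET : _INTENT_NAME_OFFSET + _INTENT_NAME_LEN] = bytes(
        _INTENT_NAME_LEN
    )
    struct.pack_into(end + "f", header, _VOX_OFFSET_OFFSET, float(_HDR_SIZE + 4))
    out_raw = bytes(header) + bytes(4) + data  # zero extender: no extensions

    out_path.parent.mkdir(parents=True, exist_ok=True)
    if was_gz or out_path.suffix == ".gz":
        out_path.write_bytes(gzip.compress(out_raw, mtime=0))
    else:
        out_path.write_bytes(out_raw)

    return ScrubReport(
        file=str(in_path),
        fields_cleared=[("descrip", _DESCRIP_LEN), ("intent_name", _INTENT_NAME_LEN)],
        extensions_removed=n_ext,
        data_checksum_before=hashlib.sha256(data).hexdigest(),
        data_checksum_after=hashlib.sha256(out_raw[_HDR_SIZE + 4 :]).hexdigest(),
    )


def default_denylist() -> list[str]:
    """Key patterns shipped with the package (editable via a config file)."""
    text = resources.files("megasite").joinpath("denylist_default.json").read_text()
    return json.loads(text)


def scrub_json_object(obj, denylist: list[str] | None = None):
    """Return (scrubbed object, removed key paths) for a parsed JSON value.

    Keys matching any denylist pattern (case-insensitive regex search) are
    removed recursively, including inside lists of objects; everything else
    is preserved as-is.
    """
    patterns = [re.compile(p, re.IGNORECASE) for p in (denylist or default_denylist())]
    removed: list[str] = []

    def walk(node, path):
        if isinstance(node, dict):
            out = {}
            for key, val in node.items():
                here = f"{path}.{key}" if path else key
                if any(p.search(key) for p in patterns):
                    removed.append(here)
                else:
                    out[key] = walk(val, here)
            return out
        if isinstance(node, list):
            return [walk(v, f"{path}[{i}]") for i, v in enumerate(node)]
        return node

    return walk(obj, ""), removed


def scrub_json(in_path, out_path, denylist: list[str] | None = None) -> ScrubReport:
    """Scrub a JSON sidecar file; writes canonical 2-space-indented JSON."""
    in_path, out_path = Path(in_path), Path(out_path)
    try:
        obj = json.loads(in_path.read_text())
    except json.JSONDecodeError as exc:
        raise FormatError(f"{in_path}: unparseable JSON ({exc})") from exc
    scrubbed, removed = scrub_json_object(obj, denylist)
    out_path.parent.mkdir(parents=True, exist_ok=True)
    out_path.write_text(json.dumps(scrubbed, indent=2, sort_keys=True) + "\n")
    return ScrubReport(file=str(in_path), json_keys_removed=removed)
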