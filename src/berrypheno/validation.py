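"""Lightweight structural validation against the shipped JSON schemas.

The package ships JSON-schema documents describing its interchange formats
(detection records and the evaluation report).  This module implements the
small subset of JSON-schema keywords those documents use (``type``,
``required``, ``properties``, ``items``, ``enum``, ``minimum``, ``maximum``,
``additionalProperties`` as a schema), enough to validate the package's own
output without an external validator dependency.
"""

from __future__ import annotations

import json
from importlib import resources

__all__ = ["load_schema", "validate", "SchemaError"]

_TYPES = {
    "object": dict,
    "array": list,
    "string": str,
    "number": (int, float),
    "integer": int,
    "boolean": bool,
    "null": type(None),
}


class SchemaError(ValueError):
    """The instance does not conform to the schema."""


def load_schema(name: str) -> dict:
    """Load a schema shipped with the package, e.g. ``"detections"``."""
    text = resources.files("berrypheno.schemas").joinpath(f"{name}.schema.json").read_text()
    return json.loads(text)


def validate(instance, schema: dict, path: str = "$") -> None:
    """Raise :class:`SchemaError` if ``instance`` violates ``schema``."""
    stype = schema.get("type")
    if stype is not None:
        expected = _TYPES[stype]
        ok = isinstance(instance, expected)
        if stype == "number" and isinstance(instance, bool):
            ok = False
        if stype == "integer" and isinstance(instance, bool):
            ok = False
        if not ok:
            raise SchemaError(f"{path}: expected {stype}, got {type(instance).__name__}")
    if "enum" in schema and instance not in schema["enum"]:
        raise SchemaError(f"{path}: {instance!r} not in {schema['enum']}")
    if isinstance(instance, (int, float)) and not isinstance(instance, bool):
        if "minimum" in schema and instance < schema["minimum"]:
            raise SchemaError(f"{path}: {instance} < minimum {schema['minimum']}")
        if "maximum" in schema and instance > schema["maximum"]:
            raise SchemaError(f"{path}: {instance} > maximum {schema['maximum']}")
    if isinstance(instance, dict):
        for key in schema.get("required", []):
            if key not in instance:
                raise SchemaError(f"{path}: missing required key {key!r}")
        props = schema.get("properties", {})
        extra = schema.get("additionalProperties")
        for key, value in instance.items():
            if key in props:
                validate(value, props[key], f"{path}.{key}")
            elif isinstance(extra, dict):
                validate(value, extra, f"{path}.{key}")
    if isinstance(instance, list) and "items" in schema:
        for i, item in enumerate(instance):
            validate(item, schema["items"], f"{path}[{i}]")
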