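"""Published CSV column schemas and validation.

Each stage's output CSV has a schema file shipped with the package
(``inclusiontools/schemas/*.json``) naming its columns and dtypes; every
output is validated against its schema before being written, and inputs can
be validated on read.
"""

from __future__ import annotations

import json
from importlib import resources

import pandas as pd

from .errors import SchemaError

_DTYPE_CHECKS = {
    "int": pd.api.types.is_integer_dtype,
    "float": pd.api.types.is_numeric_dtype,
    "bool": lambda s: pd.api.types.is_bool_dtype(s)
    or pd.api.types.is_integer_dtype(s),
    "str": lambda s: pd.api.types.is_object_dtype(s)
    or pd.api.types.is_string_dtype(s),
    "any": lambda s: True,
}


def load_schema(name: str) -> dict:
    path = resources.files("inclusiontools") / "schemas" / f"{name}.json"
    return json.loads(path.read_text())


def validate(df: pd.DataFrame, schema_name: str) -> None:
    """Raise :class:`SchemaError` if the frame violates the named schema."""
    schema = load_schema(schema_name)
    for col in schema["columns"]:
        name = col["name"]
        if name not in df.columns:
            raise SchemaError(f"{schema_name}: missing column {name!r}")
        if not _DTYPE_CHECKS[col["dtype"]](df[name]):
            raise SchemaError(
                f"{schema_name}: column {name!r} is not {col['dtype']} "
                f"(got {df[name].dtype})"
            )
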