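"""Data-type registry and shared typed-instance base.

Each data type translates its Science API into key-value pairs persisted
through the versioned storage core.  New types register themselves in
``TYPE_REGISTRY`` (name → class) at import time.
"""

from __future__ import annotations

from .core import Service, VersionedContext
from .dag import DataInstance, Repo

__all__ = ["TYPE_REGISTRY", "BaseInstance"]

TYPE_REGISTRY: dict[str, type] = {}


def register(name: str):
    def deco(cls):
        TYPE_REGISTRY[name] = cls
        cls.type_name = name
        return cls
    return deco


class BaseInstance:
    """A typed data instance bound to one repo and the service store."""

    type_name = "base"

    def __init__(self, service: Service, repo: Repo, instance: DataInstance):
        self.service = service
        self.repo = repo
        self.instance = instance

    @property
    def name(self) -> str:
        return self.instance.name

    @property
    def data_id(self) -> int:
        return self.instance.data_id

    @property
    def config(self) -> dict:
        return self.instance.config

    def ctx(self, version: str) -> VersionedContext:
        self.repo.node(version)
        return VersionedContext(self.service, self.repo, self.instance, version)


# Import type implementations so registration runs on package import.
from . import grayscale, labels, annotations, keyvalue  # noqa: E402,F401
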