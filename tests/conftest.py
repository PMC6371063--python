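import json

import numpy as np
import pytest
from hypothesis import settings

import voxeldag as V

settings.register_profile("repro", derandomize=True)
settings.load_profile("repro")


@pytest.fixture
def svc():
    return V.Service(uuid_factory=V.seeded_uuid_factory(1234))


@pytest.fixture
def repo(svc):
    return svc.create_repo(alias="test")


@pytest.fixture
def small_seg():
    """64³ blob segmentation with 12 labels plus its ground-truth census."""
    spec = V.SyntheticSpec(extent=(64, 64, 64), n_labels=12, seed=7)
    return V.make_segmentation(spec)


def build_chain(repo, n):
    """Commit-and-extend the master branch n times; returns uuids root..leaf."""
    chain = [repo.root_uuid]
    for i in range(n):
        repo.commit(chain[-1], f"v{i}")
        chain.append(repo.new_version(chain[-1]))
    return chain


class Client:
    """Minimal in-process driver for the WSGI Science API."""

    def __init__(self, service):
        from voxeldag.http import ScienceAPI
        self.app = ScienceAPI(service)

    def request(self, method, path, body=b""):
        if isinstance(body, (dict, list)):
            body = json.dumps(body).encode()
        return self.app.handle(method, path, body)

    def json(self, method, path, body=b"", expect=200):
        status, ctype, payload = self.request(method, path, body)
        assert status == expect, (status, payload)
        return json.loads(payload)

    def raw(self, method, path, body=b"", expect=200):
        status, ctype, payload = self.request(method, path, body)
        assert status == expect, (status, payload)
        return payload


@pytest.fixture
def client(svc):
    return Client(svc)
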