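from datetime import datetime, timezone

import pytest
from hypothesis import HealthCheck, settings

from flavorwatch.corpus import Post
from flavorwatch.taxonomy import bundled_taxonomy

settings.register_profile(
    "ci",
    derandomize=True,
    deadline=None,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("ci")


@pytest.fixture(scope="session")
def taxonomy():
    return bundled_taxonomy()


@pytest.fixture
def make_post():
    def _make(text, *, id="p0", author="jane_doe", platform="other",
              when="2016-06-16T12:00:00"):
        ts = datetime.fromisoformat(when).replace(tzinfo=timezone.utc)
        return Post(id=id, platform=platform, author=author, timestamp=ts, text=text)

    return _make
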