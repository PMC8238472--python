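import pytest

from personamine import (
    Corpus,
    PostRecord,
    UserRecord,
    generate_corpus,
    rsdd_like,
)


@pytest.fixture
def two_user_corpus() -> Corpus:
    """Two personas: u1 positive with 2 posts (one with non-ASCII body), u2 control."""
    return Corpus(
        name="fixture",
        unit="user",
        records=[
            UserRecord(
                user_id="u1",
                label="positive",
                posts=[
                    PostRecord(post_id="u1_p0", title="late night",
                               body="I can't sleep again", created_utc=100),
                    PostRecord(post_id="u1_p1", body="I'm so tired 😔",
                               created_utc=200),
                ],
            ),
            UserRecord(
                user_id="u2",
                label="control",
                posts=[PostRecord(post_id="u2_p0", body="went for a run today",
                                  created_utc=150)],
            ),
        ],
    )


@pytest.fixture(scope="session")
def rsdd_corpus() -> Corpus:
    """The strongly separated preset at its default size (200 users/class)."""
    return generate_corpus(rsdd_like(seed=0))


def _post(pid: str, title: str | None, body: str) -> PostRecord:
    return PostRecord(post_id=pid, title=title, body=body)


@pytest.fixture
def curation_posts() -> list[PostRecord]:
    """12 posts engineered so the three stages remove 2, 3 and 1 post."""
    return [
        _post("p01", "Share your story here",
              "a long narrative about sleepless nights that goes on for a while"),
        _post("p02", "Volunteers needed for a study on motherhood",
              "we are recruiting new mothers for an interview about daily routines"),
        _post("p03", None, "https://example.com/help"),
        _post("p04", "feeling low", "Thank you for the support"),
        _post("p05", None, "ok thanks"),
        _post("p06", "bad week", "I feel my ppd is back and it scares me"),
        _post("p07", "struggling at 3 months postpartum",
              "I have been awake all night with the baby again"),
        _post("p08", None, "some days are harder than others but we manage"),
        _post("p09", "advice needed",
              "my toddler refuses to nap and I am exhausted every day"),
        _post("p10", None, "the pediatrician said everything looks fine at the checkup"),
        _post("p11", "small win", "we finally slept four hours in a row last night"),
        _post("p12", None, "looking for meal ideas that are quick and healthy"),
    ]


CURATION_SURVIVOR_IDS = {"p07", "p08", "p09", "p10", "p11", "p12"}
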