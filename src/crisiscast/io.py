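"""Plain-text serialization of every pipeline artifact.

Formats: JSONL for articles and semantic frames, word2vec text for
embeddings, CSV for the world, panels, features, screening results and
predictions.  Months and reporting periods are written as 'YYYY-MM'.
"""

from __future__ import annotations

import json
from pathlib import Path

import pandas as pd

from crisiscast.world import Calendar, GeoHierarchy


def write_jsonl(records: list[dict], path: str | Path) -> None:
    with open(path, "w") as fh:
        for rec in records:
            fh.write(json.dumps(rec) + "\n")


def read_jsonl(path: str | Path) -> list[dict]:
    with open(path) as fh:
        return [json.loads(line) for line in fh if line.strip()]


def write_world(world: GeoHierarchy, calendar: Calendar, path: str | Path) -> None:
    payload = {
        "districts": list(world.districts),
        "province_of": world.province_of,
        "country_of_province": world.country_of_province,
        "names": world.names,
        "months": [str(m) for m in calendar.months],
        "regime_switch": str(calendar.regime_switch),
    }
    Path(path).write_text(json.dumps(payload, indent=1))


def read_world(path: str | Path) -> tuple[GeoHierarchy, Calendar]:
    payload = json.loads(Path(path).read_text())
    world = GeoHierarchy(
        districts=tuple(payload["districts"]),
        province_of=payload["province_of"],
        country_of_province=payload["country_of_province"],
        names=payload.get("names", {}),
    )
    months = pd.PeriodIndex(payload["months"], freq="M")
    calendar = Calendar(months=months, regime_switch=pd.Period(payload["regime_switch"], freq="M"))
    return world, calendar


def write_ipc(ipc: pd.DataFrame, path: str | Path) -> None:
    out = ipc.copy()
    out["period_end_month"] = out["period"].astype(str)
    out[["district_id", "period_end_month", "phase"]].to_csv(path, index=False)


def read_ipc(path: str | Path) -> pd.DataFrame:
    df = pd.read_csv(path)
    df["period"] = pd.PeriodIndex(df["period_end_month"], freq="M")
    return df[["district_id", "period", "phase"]]


def write_factors(factors: pd.DataFrame, path: str | Path) -> None:
    out = factors.copy()
    out["month"] = out["month"].astype(str)
    out = out.rename(columns={"factor": "factor_name"})
    out[["unit_id", "level", "month", "factor_name", "value"]].to_csv(path, index=False)


def read_factors(path: str | Path) -> pd.DataFrame:
    return pd.read_csv(path, dtype={"month": str}).rename(columns={"factor_name": "factor"})


def write_static(static: pd.DataFrame, path: str | Path) -> None:
    out = static.rename(columns={"attr": "attr_name"})
    out[["district_id", "attr_name", "value"]].to_csv(path, index=False)


def read_static(path: str | Path) -> pd.DataFrame:
    return pd.read_csv(path).rename(columns={"attr_name": "attr"})


def write_news_factors(news: pd.DataFrame, path: str | Path) -> None:
    out = news.copy()
    out["month"] = out["month"].astype(str)
    out.to_csv(path, index=False)


def read_news_factors(path: str | Path) -> pd.DataFrame:
    return pd.read_csv(path, dtype={"month": str})


def write_features(features: pd.DataFrame, path: str | Path) -> None:
    features.to_csv(path, index=False)


def read_features(path: str | Path) -> pd.DataFrame:
    return pd.read_csv(path)


def write_screen(screen: pd.DataFrame, path: str | Path) -> None:
    screen.to_csv(path, index=False)


def read_screen(path: str | Path) -> pd.DataFrame:
    return pd.read_csv(path)


def write_predictions(predictions: pd.DataFrame, path: str | Path) -> None:
    out = predictions.copy()
    out["period"] = out["period"].astype(str)
    out.to_csv(path, index=False)


def read_predictions(path: str | Path) -> pd.DataFrame:
    df = pd.read_csv(path)
    df["period"] = pd.PeriodIndex(df["period"], freq="M")
    return df
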