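"""FCS reading/writing: round trips, hand-packed binary oracles, harmonization."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from flowimpute.fcsio import (
    ChannelDescriptor,
    EventMatrix,
    FcsFormatError,
    harmonize_channels,
    read_fcs,
    write_fcs,
)


def build_fcs_bytes(data, byteord="1,2,3,4", datatype="F", pnb=None, extra_kw=None):
    """Hand-build a minimal FCS 3.1 file, independent of write_fcs."""
    data = np.asarray(data)
    n_tot, n_par = data.shape
    d = "/"
    kw = {
        "$MODE": "L",
        "$DATATYPE": datatype,
        "$BYTEORD": byteord,
        "$PAR": str(n_par),
        "$TOT": str(n_tot),
        "$NEXTDATA": "0",
    }
    for i in range(1, n_par + 1):
        kw[f"$P{i}N"] = f"CH{i}"
        kw[f"$P{i}B"] = str(pnb or (32 if datatype == "F" else 64))
        kw[f"$P{i}E"] = "0,0"
        kw[f"$P{i}R"] = "262144"
    kw.update(extra_kw or {})
    endian = "<" if byteord.startswith("1") else ">"
    if datatype == "F":
        payload = data.astype(endian + "f4").tobytes()
    elif datatype == "D":
        payload = data.astype(endian + "f8").tobytes()
    else:
        payload = data.astype(endian + f"u{(pnb or 32) // 8}").tobytes()
    # assemble with offsets solved by fixed-point iteration
    begin = end = 0
    for _ in range(6):
        items = dict(kw, **{"$BEGINDATA": str(begin), "$ENDDATA": str(end)})
        text = d + "".join(f"{k}{d}{v}{d}" for k, v in items.items())
        tb = 58
        te = tb + len(text.encode()) - 1
        nb, ne = te + 1, te + len(payload)
        if (nb, ne) == (begin, end):
            break
        begin, end = nb, ne
    header = (
        b"FCS3.1    "
        + f"{tb:>8}{te:>8}{begin:>8}{end:>8}{0:>8}{0:>8}".encode()
    )
    return header + text.encode() + payload


class TestRoundTrip:
    def test_random_matrix_roundtrips_within_float32_eps(self, small_matrix, tmp_path):
        p = tmp_path / "rt.fcs"
        write_fcs(small_matrix, p)
        back = read_fcs(p)
        np.testing.assert_allclose(
            back.data, small_matrix.data, rtol=1e-6, atol=1e-2
        )
        assert back.channel_names == small_matrix.channel_names
        assert back.keywords["CYT"] == "SyntheticCytometer"
        assert back.keywords["OPERATOR"] == "tester"
        assert [c.stain_name for c in back.channels] == [
            c.stain_name for c in small_matrix.channels
        ]

    def test_empty_matrix_roundtrips(self, tmp_path):
        m = EventMatrix(
            data=np.empty((0, 2)),
            channels=[ChannelDescriptor("A"), ChannelDescriptor("B")],
        )
        p = tmp_path / "empty.fcs"
        write_fcs(m, p)
        back = read_fcs(p)
        assert back.keywords["$TOT"] == "0"
        assert back.data.shape == (0, 2)

    def test_delimiter_in_keyword_value_escaped(self, tmp_path):
        m = EventMatrix(
            data=np.ones((3, 1)),
            channels=[ChannelDescriptor("A")],
            keywords={"SAMPLE": "a/b/c"},
        )
        p = tmp_path / "esc.fcs"
        write_fcs(m, p)
        # the on-disk TEXT must carry the doubled delimiter
        raw = p.read_bytes()
        assert b"a//b//c" in raw
        assert read_fcs(p).keywords["SAMPLE"] == "a/b/c"

    def test_escaped_delimiter_parsed_from_handbuilt_text(self, tmp_path):
        blob = build_fcs_bytes(
            np.ones((2, 1)), extra_kw={"NOTE": "x//y"}  # literal 'x/y' escaped
        )
        p = tmp_path / "hb.fcs"
        p.write_bytes(blob)
        assert read_fcs(p).keywords["NOTE"] == "x/y"

    def test_nonfinite_values_rejected_on_write(self, tmp_path):
        m = EventMatrix(
            data=np.array([[np.nan]]), channels=[ChannelDescriptor("A")]
        )
        with pytest.raises(ValueError, match="non-finite"):
            write_fcs(m, tmp_path / "bad.fcs")

    @settings(max_examples=25, deadline=None, derandomize=True)
    @given(
        n=st.integers(1, 50),
        k=st.integers(1, 8),
        seed=st.integers(0, 2**31 - 1),
    )
    def test_roundtrip_property(self, n, k, seed, tmp_path_factory):
        rng = np.random.default_rng(seed)
        m = EventMatrix(
            data=rng.normal(scale=1e4, size=(n, k)),
            channels=[ChannelDescriptor(f"C{i}") for i in range(k)],
            keywords={"K1": "v/1", "K2": "plain"},
        )
        p = tmp_path_factory.mktemp("rt") / "f.fcs"
        write_fcs(m, p)
        back = read_fcs(p)
        np.testing.assert_array_equal(
            back.data, m.data.astype(np.float32).astype(np.float64)
        )
        assert back.keywords["K1"] == "v/1"


class TestReadVariants:
    @pytest.mark.parametrize("byteord", ["1,2,3,4", "4,3,2,1"])
    @pytest.mark.parametrize("datatype", ["F", "D"])
    def test_endianness_and_float_widths(self, byteord, datatype, tmp_path):
        rng = np.random.default_rng(0)
        data = rng.uniform(0, 1e5, size=(20, 3))
        p = tmp_path / "v.fcs"
        p.write_bytes(build_fcs_bytes(data, byteord=byteord, datatype=datatype))
        back = read_fcs(p)
        expect = data.astype(np.float32) if datatype == "F" else data
        np.testing.assert_allclose(back.data, expect.astype(np.float64), rtol=1e-6)

    @pytest.mark.parametrize("byteord", ["1,2,3,4", "4,3,2,1"])
    def test_integer_16bit_hand_packed(self, byteord, tmp_path):
        # hand-packed oracle: $DATATYPE=I, $PnB=16, values {0, 1023}
        data = np.array([[0, 1023], [1023, 0], [7, 42]], dtype=np.uint16)
        p = tmp_path / "i16.fcs"
        p.write_bytes(
            build_fcs_bytes(data, byteord=byteord, datatype="I", pnb=16)
        )
        back = read_fcs(p)
        assert back.data.dtype == np.float64
        np.testing.assert_array_equal(
            back.data, np.array([[0.0, 1023.0], [1023.0, 0.0], [7.0, 42.0]])
        )

    def test_big_and_little_endian_read_identically(self, tmp_path):
        data = np.arange(12, dtype=float).reshape(4, 3) * 3.5
        pl, pb = tmp_path / "le.fcs", tmp_path / "be.fcs"
        pl.write_bytes(build_fcs_bytes(data, byteord="1,2,3,4"))
        pb.write_bytes(build_fcs_bytes(data, byteord="4,3,2,1"))
        np.testing.assert_array_equal(read_fcs(pl).data, read_fcs(pb).data)

    def test_tot_inconsistent_with_data_length_errors(self, tmp_path):
        blob = build_fcs_bytes(np.ones((3, 2)), extra_kw={"$TOT": "9"})
        p = tmp_path / "badtot.fcs"
        p.write_bytes(blob)
        with pytest.raises(FcsFormatError, match=r"\$TOT"):
            read_fcs(p)

    def test_unsupported_magic_errors(self, tmp_path):
        p = tmp_path / "old.fcs"
        p.write_bytes(b"FCS2.0" + b" " * 100)
        with pytest.raises(FcsFormatError, match="FCS3.0 or FCS3.1"):
            read_fcs(p)

    def test_offset_mismatch_names_both_values(self, tmp_path):
        blob = build_fcs_bytes(np.ones((2, 2)))
        # corrupt $BEGINDATA to disagree with the HEADER offset
        blob = blob.replace(b"$BEGINDATA/", b"$BEGINDATA/9", 1)
        p = tmp_path / "off.fcs"
        p.write_bytes(blob)
        with pytest.raises(FcsFormatError, match="disagrees"):
            read_fcs(p)

    def test_nondefault_mode_rejected(self, tmp_path):
        blob = build_fcs_bytes(np.ones((2, 2)), extra_kw={"$MODE": "C"})
        p = tmp_path / "mode.fcs"
        p.write_bytes(blob)
        with pytest.raises(FcsFormatError, match="list mode"):
            read_fcs(p)

    def test_chained_datasets_warn_and_first_read(self, tmp_path):
        blob = build_fcs_bytes(np.ones((2, 2)), extra_kw={"$NEXTDATA": "500"})
        p = tmp_path / "chain.fcs"
        p.write_bytes(blob)
        with pytest.warns(UserWarning, match="NEXTDATA"):
            back = read_fcs(p)
        assert back.n_events == 2


class TestHarmonize:
    def _mk(self, names, stains=None, path=""):
        k = len(names)
        chans = [
            ChannelDescriptor(n, stain_name=(stains or {}).get(n))
            for n in names
        ]
        data = np.arange(5 * k, dtype=float).reshape(5, k)
        return EventMatrix(data=data, channels=chans, source_path=path)

    def test_permuted_backbone_orders_align(self):
        f1 = self._mk(["A", "B", "C", "X"])
        f2 = self._mk(["C", "A", "X", "B"])
        out = harmonize_channels([f1, f2], ["A", "B", "C"])
        assert out[0].channel_names[:3] == ["A", "B", "C"]
        assert out[1].channel_names[:3] == ["A", "B", "C"]
        # column content followed its channel
        np.testing.assert_array_equal(out[1].column("A"), f2.column("A"))
        np.testing.assert_array_equal(out[1].column("C"), f2.column("C"))
        # non-backbone retained
        assert "X" in out[0].channel_names and "X" in out[1].channel_names

    def test_stain_name_fallback_matches(self, caplog):
        import logging

        f = self._mk(["FL1-A", "FL2-A"], stains={"FL1-A": "CD3"})
        with caplog.at_level(logging.INFO, logger="flowimpute.fcsio"):
            out = harmonize_channels([f], ["CD3"])
        assert out[0].channel_names[0] == "CD3"
        assert any("$PnS fallback" in r.message for r in caplog.records)

    def test_missing_backbone_names_offending_file(self):
        f1 = self._mk(["A", "B"], path="good.fcs")
        f2 = self._mk(["A", "Z"], path="bad.fcs")
        with pytest.raises(KeyError, match="bad.fcs"):
            harmonize_channels([f1, f2], ["A", "B"])
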