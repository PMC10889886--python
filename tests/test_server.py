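"""Command server: broadcast gating, single-client lock, dual acknowledgement."""

import json
import logging
import socket
import threading
import time

import pytest

from quadpure.client import ClientSession
from quadpure.errors import ServerBusyError, ServerError
from quadpure.server import PurifierServer


@pytest.fixture
def server(registry, free_udp_port):
    srv = PurifierServer(registry=registry, status_port=free_udp_port,
                         broadcast_interval_s=0.05)
    with srv:
        yield srv


class RawClient:
    """Bare-wire client for observing the exact reply stream."""

    def __init__(self, server):
        self.sock = socket.create_connection(
            (server.host, server.command_port), timeout=5.0)
        self.file = self.sock.makefile("rwb")
        self.greeting = self.read()

    def send(self, **record):
        self.file.write(json.dumps(record).encode() + b"\n")
        self.file.flush()

    def read(self):
        line = self.file.readline()
        if not line:
            return None
        return json.loads(line)

    def read_non_status(self):
        while True:
            msg = self.read()
            if msg is None or msg["msg_type"] != "STATUS":
                return msg

    def close(self):
        self.sock.close()


class TestBroadcast:
    def test_idle_server_broadcasts_each_interval(self, server, free_udp_port):
        sock = socket.socket(socket.AF_INET, socket.SOCK_DGRAM)
        sock.setsockopt(socket.SOL_SOCKET, socket.SO_REUSEADDR, 1)
        sock.bind(("127.0.0.1", free_udp_port))
        sock.settimeout(1.0)
        datagrams = [json.loads(sock.recvfrom(65536)[0]) for _ in range(3)]
        sock.close()
        assert all(d["msg_type"] == "STATUS" for d in datagrams)
        assert all(d["payload"]["busy"] is False for d in datagrams)

    def test_broadcasts_cease_while_connected_and_resume_after(self, server):
        with ClientSession(server.host, server.command_port):
            time.sleep(3 * server.broadcast_interval_s)
            start = server.broadcast_count
            time.sleep(4 * server.broadcast_interval_s)
            assert server.broadcast_count - start <= 1   # within one interval
        time.sleep(4 * server.broadcast_interval_s)
        assert server.broadcast_count > start + 1        # resumed


class TestSingleClientLock:
    def test_second_client_refused_with_holder_identity(self, server):
        with ClientSession(server.host, server.command_port):
            with pytest.raises(ServerBusyError, match="held by"):
                ClientSession(server.host, server.command_port)

    def test_lock_freed_on_disconnect(self, server):
        a = ClientSession(server.host, server.command_port)
        a.disconnect()
        deadline = time.monotonic() + 5
        while server.client_connected and time.monotonic() < deadline:
            time.sleep(0.01)
        b = ClientSession(server.host, server.command_port)   # accepted
        b.disconnect()

    def test_exactly_one_holder_under_concurrent_connections(self, server):
        results = []
        barrier = threading.Barrier(8)

        def attempt():
            barrier.wait()
            try:
                session = ClientSession(server.host, server.command_port)
                results.append(session)
            except ServerBusyError:
                results.append(None)

        threads = [threading.Thread(target=attempt) for _ in range(8)]
        for t in threads:
            t.start()
        for t in threads:
            t.join(timeout=10)
        winners = [r for r in results if r is not None]
        assert len(winners) == 1
        winners[0].disconnect()

    def test_force_disconnect_mid_run_aborts_and_frees_lock(self, server):
        from quadpure.protocol import Protocol, ProtocolStep, RunState, StepKind
        errors = []
        # a HOLD step parks the run mid-protocol until the operator resumes,
        # so the run is deterministically in flight when we sever the client
        proto = Protocol(name="holdy", steps=[
            ProtocolStep(kind=StepKind.EQUILIBRATE, buffer_port=1, volume_cv=2),
            ProtocolStep(kind=StepKind.HOLD),
        ])

        def run_client():
            try:
                with ClientSession(server.host, server.command_port) as sess:
                    sess.select_config("histrap_1ml")
                    sess.run_protocol(proto)
            except (ServerError, OSError) as exc:
                errors.append(exc)

        t = threading.Thread(target=run_client)
        t.start()
        deadline = time.monotonic() + 5
        while time.monotonic() < deadline:
            engine = server.engine
            if engine is not None and engine.run.state is RunState.HOLDING:
                break
            time.sleep(0.01)
        else:
            pytest.fail("run never reached the holding state")
        server.force_disconnect()
        t.join(timeout=10)
        assert errors             # the client saw its connection sever
        deadline = time.monotonic() + 5
        while server.client_connected and time.monotonic() < deadline:
            time.sleep(0.01)
        assert not server.client_connected
        # rig was reset to a safe, unconfigured state; lock is free again
        assert server.controller.config is None
        with ClientSession(server.host, server.command_port) as sess:
            assert sess.status()["config"] is None


class TestDispatch:
    def test_every_request_gets_ack_then_exactly_one_terminal(self, server):
        raw = RawClient(server)
        for rid, (cmd, args) in enumerate([
                ("list_configs", {}),
                ("select_config", {"name": "histrap_1ml"}),
                ("status", {}),
        ], start=1):
            raw.send(msg_type="REQUEST", request_id=rid, command=cmd, args=args)
        replies = [raw.read_non_status() for _ in range(6)]
        raw.close()
        kinds = [(m["msg_type"], m["request_id"]) for m in replies]
        assert kinds == [("ACK", 1), ("COMPLETE", 1),
                         ("ACK", 2), ("COMPLETE", 2),
                         ("ACK", 3), ("COMPLETE", 3)]

    def test_hardware_command_before_select_config(self, server):
        raw = RawClient(server)
        raw.send(msg_type="REQUEST", request_id=1, command="run_pump",
                 args={"channel": 1, "volume_ml": 1.0, "rate_ml_min": 1.0})
        ack = raw.read_non_status()
        err = raw.read_non_status()
        raw.close()
        assert ack["msg_type"] == "ACK"
        assert err["msg_type"] == "ERROR"
        assert err["error"]["code"] == "configuration"

    def test_unknown_command_is_acked_then_errored(self, server):
        raw = RawClient(server)
        raw.send(msg_type="REQUEST", request_id=1, command="frobnicate")
        assert raw.read_non_status()["msg_type"] == "ACK"
        err = raw.read_non_status()
        raw.close()
        assert err["msg_type"] == "ERROR"

    def test_malformed_args_are_acked_then_errored(self, server):
        raw = RawClient(server)
        raw.send(msg_type="REQUEST", request_id=1, command="select_config",
                 args={"wrong_key": True})
        assert raw.read_non_status()["msg_type"] == "ACK"
        err = raw.read_non_status()
        raw.close()
        assert err["msg_type"] == "ERROR"
        assert err["error"]["code"] == "validation"

    def test_select_config_must_not_stack(self, server):
        from quadpure.errors import ConfigurationError
        with ClientSession(server.host, server.command_port) as sess:
            sess.select_config("histrap_1ml")
            # server-side errors come back as the typed exception
            with pytest.raises(ConfigurationError, match="already active"):
                sess.request("select_config", name="histrap_5ml")

    def test_run_control_outside_a_run_is_an_error(self, server):
        from quadpure.errors import RunStateError
        with ClientSession(server.host, server.command_port) as sess:
            sess.select_config("histrap_1ml")
            with pytest.raises(RunStateError):
                sess.request("pause")


class TestLogging:
    def test_all_messages_appear_in_the_debug_log(self, registry,
                                                  free_udp_port, caplog):
        with caplog.at_level(logging.DEBUG, logger="quadpure.server"):
            with PurifierServer(registry=registry, status_port=free_udp_port,
                                broadcast_interval_s=0.05) as srv:
                raw = RawClient(srv)
                raw.send(msg_type="REQUEST", request_id=1,
                         command="list_configs")
                raw.read_non_status()
                raw.read_non_status()
                raw.close()
                deadline = time.monotonic() + 5
                while srv.client_connected and time.monotonic() < deadline:
                    time.sleep(0.01)
                time.sleep(3 * srv.broadcast_interval_s)  # idle broadcasts
        text = caplog.text
        assert '"msg_type": "REQUEST"' in text or 'list_configs' in text
        assert '"msg_type":"ACK"' in text
        assert '"msg_type":"COMPLETE"' in text
        assert "broadcast" in text
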