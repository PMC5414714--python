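/root/pkg/src/tumortyperprofiles.pypatterns.pyannotation.py__init__.pysynthetic.pypipeline.py   dags.py��!��0Ǭ3����         votes.py�׆,�2 ����         boost.pyZ��Ӥ���                                         �   r����!��0Ǭ3����         �   F����׆,�2 ����         cli.py��8y��M����         �   ����V�mǶ�;����         �   �����k @3��@����         �   ������2�����         �   x����׆,�2 ����         o).7:A�^]#o).7:A�^]#��������� �    �������
      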