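/root/pkg/src/tumortyperprofiles.pypatterns.pyannotation.py__init__.pysynthetic.pypipeline.py   dags.py�R��� �����          votes.py
��kGn�����          boost.pyZ��Ӆ���                                         �   r���!�o�(����          �   F�����I?�1Q����          cli.py���q*�+N�����          �   ����V�mǶ�;����         �   �����k @3��@����         �   ������2�����         �   x���wou�1Jz����          o).7:A�^]#o).7:A�^]#��������� �    �������
      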